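"""Ranking of point mutations and combinatorial mutants by Δlog2E.

Point mutations are scored per chemokine-class scope by two criteria: the
mean Δlog2E over in-scope targets (overall affinity) and the peak Δlog2E
(best single target, capturing binding diversity). At each parent position
the best mutation by each criterion is kept, thresholds applied, and the
top-N taken per class pool; the CC and CXnC pools are then united.

Combinatorial mutants are ranked by the *median* Δlog2E over a scope, which
rewards breadth of binding rather than a few strong targets, and grouped
into CM-max / CM-min / CM-maxCC / CM-maxCXnC.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

from .enrichment import TargetPanel

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class Mutation(NamedTuple):
    """A single substitution, named in the conventional style, e.g. Y5W."""

    position: int  # 1-based position in the parent
    from_aa: str
    to_aa: str

    def __str__(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"

    @classmethod
    def parse(cls, text: str) -> "Mutation":
        m = re.fullmatch(r"([A-Y])(\d+)([A-Y])", text)
        if not m:
            raise ValueError(f"cannot parse mutation {text!r}")
        return cls(int(m.group(2)), m.group(1), m.group(3))


def validate_mutation(mut: Mutation, parent: str) -> None:
    if not 1 <= mut.position <= len(parent):
        raise ValueError(f"{mut}: position outside parent of length {len(parent)}")
    if parent[mut.position - 1] != mut.from_aa:
        raise ValueError(
            f"{mut}: parent has {parent[mut.position - 1]} at position {mut.position}"
        )
    if mut.to_aa == mut.from_aa:
        raise ValueError(f"{mut}: substitution to the parental residue")


def mutations_from_sequence(parent: str, seq: str) -> frozenset[Mutation]:
    """Mutation set of a variant relative to the parent (equal lengths)."""
    if len(seq) != len(parent):
        raise ValueError("variant and parent lengths differ")
    return frozenset(
        Mutation(i + 1, p, s) for i, (p, s) in enumerate(zip(parent, seq)) if p != s
    )


@dataclass(frozen=True)
class MutationEffect:
    mutation: Mutation
    scope: str  # ALL / CC / CXnC
    mean_delta: float
    peak_delta: float
    n_targets: int

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("n_targets must be positive")
        if self.peak_delta < self.mean_delta - 1e-12:
            raise ValueError("peak Δlog2E cannot be below the mean")


@dataclass(frozen=True)
class SelectionConfig:
    peak_threshold: float = 5.0
    mean_threshold: float = 0.55
    top_n_cc: int = 10
    top_n_cxnc: int = 12
    combine: str = "or"  # keep a mutation if either threshold passes ("and" available)

    def __post_init__(self) -> None:
        if self.top_n_cc < 1 or self.top_n_cxnc < 1:
            raise ValueError("top_n must be >= 1")
        if self.combine not in ("or", "and"):
            raise ValueError("combine must be 'or' or 'and'")


def summarize_mutation_effects(
    tbl: pd.DataFrame, panel: TargetPanel, parent: str, scope: str = "ALL"
) -> list[MutationEffect]:
    """Per-mutation mean and peak Δlog2E over the targets of one class scope.

    Every non-parent variant in the table must be a single mutant; the parent
    row is skipped (its Δlog2E is identically 0).
    """
    in_scope = set(panel.names(scope))
    sub = tbl[tbl["target"].isin(in_scope)]
    effects = []
    for variant, grp in sub.groupby("variant", sort=True):
        muts = mutations_from_sequence(parent, variant)
        if not muts:
            continue  # parent
        if len(muts) != 1:
            raise ValueError(f"variant {variant} is not a single mutant of the parent")
        (mut,) = muts
        deltas = grp["delta_log2E"]
        effects.append(
            MutationEffect(
                mutation=mut,
                scope=scope,
                mean_delta=float(deltas.mean()),
                peak_delta=float(deltas.max()),
                n_targets=len(deltas),
            )
        )
    return effects


def _pool_select(
    effects: list[MutationEffect], top_n: int, cfg: SelectionConfig
) -> list[MutationEffect]:
    # keep, per position, the best mutation by mean and the best by peak
    by_pos: dict[int, list[MutationEffect]] = {}
    for e in effects:
        by_pos.setdefault(e.mutation.position, []).append(e)
    candidates: set[Mutation] = set()
    per_pos_best: list[MutationEffect] = []
    for pos_effects in by_pos.values():
        best_mean = max(pos_effects, key=lambda e: (e.mean_delta, e.peak_delta))
        best_peak = max(pos_effects, key=lambda e: (e.peak_delta, e.mean_delta))
        for e in (best_mean, best_peak):
            if e.mutation not in candidates:
                candidates.add(e.mutation)
                per_pos_best.append(e)
    if cfg.combine == "or":
        kept = [
            e for e in per_pos_best
            if e.peak_delta >= cfg.peak_threshold or e.mean_delta >= cfg.mean_threshold
        ]
    else:
        kept = [
            e for e in per_pos_best
            if e.peak_delta >= cfg.peak_threshold and e.mean_delta >= cfg.mean_threshold
        ]
    kept.sort(
        key=lambda e: (-e.mean_delta, -e.peak_delta, e.mutation.position, e.mutation.to_aa)
    )
    if len(kept) < top_n:
        warnings.warn(
            f"only {len(kept)} candidates pass thresholds (top_n={top_n}); returning all"
        )
    return kept[:top_n]


def select_improving_mutations(
    effects_cc: list[MutationEffect],
    effects_cxnc: list[MutationEffect],
    cfg: SelectionConfig | None = None,
) -> dict[Mutation, set[str]]:
    """Union of the per-class top-N improving mutations, with pool membership.

    Returns mutation -> subset of {"CC", "CXnC"}; a mutation selected in both
    class pools carries both labels.
    """
    cfg = cfg or SelectionConfig()
    pools: dict[Mutation, set[str]] = {}
    for label, effects, top_n in (
        ("CC", effects_cc, cfg.top_n_cc),
        ("CXnC", effects_cxnc, cfg.top_n_cxnc),
    ):
        for e in _pool_select(effects, top_n, cfg):
            pools.setdefault(e.mutation, set()).add(label)
    return pools


CM_GROUPS = ("CM-max", "CM-min", "CM-maxCC", "CM-maxCXnC")


@dataclass
class CombinatorialRanking:
    """Median-Δlog2E ranking of a combinatorial library with CM group labels."""

    table: pd.DataFrame  # variant, median_delta_all/cc/cxnc, mean_delta_all
    groups: dict[str, list[str]] = field(default_factory=dict)
    group_size: int = 5


def rank_combinatorial(
    tbl: pd.DataFrame, panel: TargetPanel, group_size: int = 5
) -> CombinatorialRanking:
    """Rank variants by median Δlog2E over ALL / CC / CXnC target scopes.

    CM-max / CM-min are the top / bottom ``group_size`` variants by the
    all-target median; CM-maxCC and CM-maxCXnC are analogous on the class
    medians. Ties break on (median, mean, sequence).
    """
    n_variants = tbl["variant"].nunique()
    if n_variants < group_size:
        raise ValueError(f"library of {n_variants} variants < group_size {group_size}")
    scopes = {"all": "ALL", "cc": "CC", "cxnc": "CXnC"}
    cols = {}
    for key, scope in scopes.items():
        names = set(panel.names(scope))
        sub = tbl[tbl["target"].isin(names)]
        cols[f"median_delta_{key}"] = sub.groupby("variant")["delta_log2E"].median()
        cols[f"mean_delta_{key}"] = sub.groupby("variant")["delta_log2E"].mean()
    table = pd.DataFrame(cols).reset_index().rename(columns={"index": "variant"})

    def top(col: str, ascending: bool) -> list[str]:
        sign = 1 if ascending else -1
        ordered = sorted(
            table.itertuples(index=False),
            key=lambda r: (
                sign * getattr(r, col),
                sign * getattr(r, col.replace("median", "mean")),
                r.variant,
            ),
        )
        return [r.variant for r in ordered[:group_size]]

    groups = {
        "CM-max": top("median_delta_all", ascending=False),
        "CM-min": top("median_delta_all", ascending=True),
        "CM-maxCC": top("median_delta_cc", ascending=False),
        "CM-maxCXnC": top("median_delta_cxnc", ascending=False),
    }
    return CombinatorialRanking(table=table, groups=groups, group_size=group_size)
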