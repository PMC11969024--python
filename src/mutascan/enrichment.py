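"""Selection enrichment: frequencies, log2E and Δlog2E relative to the parent.

Enrichment E of a variant is the ratio of its output (post-selection) to input
frequency, reported as log2E; Δlog2E subtracts the parental peptide's log2E
for the same target, so the parent sits at 0 by construction. Two imputation
dialects avoid infinities from zero counts:

``add_one``
    add a pseudocount of 1 to every designed-library member before
    normalising (used for total-support combinatorial libraries).
``impute_min``
    normalise observed counts only, then assign unobserved members the
    minimum observed proportion of that sample, flagged as imputed (used for
    sparse single-mutant libraries).

Variants that enrich on the non-specific control target (log2E > 0) are
excluded from all downstream analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicon import VariantCounts

MODES = ("add_one", "impute_min")


@dataclass
class FrequencyTable:
    sample_id: str
    freq: "pd.Series[float]"  # index: peptide, values in (0, 1]
    mode: str
    imputed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if (self.freq <= 0).any():
            raise ValueError("frequencies must be positive after imputation")


@dataclass(frozen=True)
class Target:
    name: str
    chem_class: str | None = None  # "CC" or "CXnC"; None for controls
    chem_type: str | None = None  # inflammatory / dual / homeostatic
    is_control: bool = False


@dataclass
class TargetPanel:
    targets: list[Target]

    def __post_init__(self) -> None:
        controls = [t for t in self.targets if t.is_control]
        if len(controls) > 1:
            raise ValueError("at most one control target per panel")
        for t in self.targets:
            if not t.is_control and t.chem_class not in ("CC", "CXnC"):
                raise ValueError(f"target {t.name}: class must be CC or CXnC")

    @property
    def control(self) -> Target | None:
        for t in self.targets:
            if t.is_control:
                return t
        return None

    def names(self, scope: str = "ALL", include_control: bool = False) -> list[str]:
        """Target names in a class scope; controls excluded unless requested."""
        out = []
        for t in self.targets:
            if t.is_control:
                if include_control:
                    out.append(t.name)
                continue
            if scope == "ALL" or t.chem_class == scope:
                out.append(t.name)
        return out


#: columns of the long-form enrichment table
ENRICHMENT_COLUMNS = [
    "variant", "target", "log2E", "delta_log2E", "input_imputed", "output_imputed",
]


def compute_frequencies(
    counts: VariantCounts, library: set[str], mode: str = "add_one"
) -> FrequencyTable:
    """Convert raw counts into per-library-member proportions.

    ``add_one``: freq_i = (c_i + 1) / Σ(c_j + 1) over the full designed
    library (zero counts included). ``impute_min``: freq_i = c_i / Σc_j over
    observed members; unobserved members get the minimum observed proportion
    and are flagged.
    """
    if not library >= set(counts.counts):
        extra = set(counts.counts) - library
        raise ValueError(f"counted peptides outside library: {sorted(extra)[:5]}")
    members = sorted(library)
    c = pd.Series({p: counts.counts.get(p, 0) for p in members}, dtype=float)
    if mode == "add_one":
        adj = c + 1.0
        return FrequencyTable(counts.sample_id, adj / adj.sum(), mode, set())
    if mode == "impute_min":
        total = c.sum()
        if total == 0:
            raise ValueError("impute_min undefined for all-zero counts")
        freq = c / total
        observed_min = freq[freq > 0].min()
        imputed = set(freq.index[freq == 0])
        freq[freq == 0] = observed_min
        return FrequencyTable(counts.sample_id, freq, mode, imputed)
    raise ValueError(f"unknown mode {mode!r}")


def compute_log2e(
    input_ft: FrequencyTable, output_ft: FrequencyTable, target: str
) -> pd.DataFrame:
    """log2(output frequency / input frequency) per variant for one target."""
    if input_ft.mode != output_ft.mode:
        raise ValueError("input and output tables use different imputation modes")
    if set(input_ft.freq.index) != set(output_ft.freq.index):
        raise ValueError("input and output tables cover different libraries")
    idx = input_ft.freq.index
    log2e = np.log2(output_ft.freq.reindex(idx) / input_ft.freq)
    return pd.DataFrame(
        {
            "variant": idx,
            "target": target,
            "log2E": log2e.to_numpy(),
            "delta_log2E": np.nan,
            "input_imputed": [v in input_ft.imputed for v in idx],
            "output_imputed": [v in output_ft.imputed for v in idx],
        }
    ).reset_index(drop=True)


def build_enrichment(
    input_ft: FrequencyTable, output_fts: dict[str, FrequencyTable]
) -> pd.DataFrame:
    """Stack per-target log2E tables into one long-form enrichment table."""
    return pd.concat(
        [compute_log2e(input_ft, ft, target) for target, ft in output_fts.items()],
        ignore_index=True,
    )


def compute_delta(tbl: pd.DataFrame, parent: str) -> pd.DataFrame:
    """Δlog2E(v, t) = log2E(v, t) − log2E(parent, t); parent rows become 0."""
    out = tbl.copy()
    parent_rows = out[out["variant"] == parent].set_index("target")["log2E"]
    missing = set(out["target"]) - set(parent_rows.index)
    if missing:
        raise ValueError(f"parent absent for targets: {sorted(missing)}")
    out["delta_log2E"] = out["log2E"] - out["target"].map(parent_rows).to_numpy()
    return out


def exclude_control_binders(
    tbl: pd.DataFrame, panel: TargetPanel
) -> tuple[pd.DataFrame, list[str]]:
    """Drop every variant enriched on the control (log2E > 0, strict).

    Returns the table restricted to non-control targets with control binders
    removed, and the sorted removal list. A panel without a control target is
    a no-op with a warning.
    """
    control = panel.control
    if control is None:
        warnings.warn("panel has no control target; control exclusion skipped")
        return tbl, []
    ctrl_rows = tbl[tbl["target"] == control.name]
    removed = sorted(ctrl_rows.loc[ctrl_rows["log2E"] > 0, "variant"].unique())
    keep = (tbl["target"] != control.name) & ~tbl["variant"].isin(removed)
    return tbl[keep].reset_index(drop=True), removed
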