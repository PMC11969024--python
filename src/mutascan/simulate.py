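"""Synthetic-data generators for every pipeline input class.

The selection simulator is the pipeline's ground truth: each variant carries
a latent per-target binding weight (additive per-mutation log2 effects plus
optional pairwise epistasis), selection is proportional retention over
rounds, and sequencing is a multinomial draw at the configured depth, so
the expected enrichment of a variant is rounds x log2(w_variant / w_parent).
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .amplicon import AmpliconScaffold, VariantCounts
from .design import CodonModel, PeptideVariant, reverse_translate
from .doseresponse import DoseResponseData, ll3
from .selection import Mutation, mutations_from_sequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class AffinityModel:
    """Latent selection weights: w(variant, target) = 2**(sum of log2 effects)."""

    parent: str
    targets: list[str]
    effects: dict[tuple[Mutation, str], float] = field(default_factory=dict)
    epistasis: dict[tuple[frozenset[Mutation], str], float] = field(default_factory=dict)
    baseline: dict[str, float] = field(default_factory=dict)

    def log2_weight(self, sequence: str, target: str) -> float:
        muts = mutations_from_sequence(self.parent, sequence)
        total = self.baseline.get(target, 0.0)
        for m in muts:
            total += self.effects.get((m, target), 0.0)
        for (pair, t), eff in self.epistasis.items():
            if t == target and pair <= muts:
                total += eff
        return total

    def weight(self, sequence: str, target: str) -> float:
        w = 2.0 ** self.log2_weight(sequence, target)
        if w <= 0:
            raise ValueError("selection weights must be strictly positive")
        return w


@dataclass(frozen=True)
class SelectionSimConfig:
    rounds: int = 3
    depth: int = 100_000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1 or self.depth < 1:
            raise ValueError("rounds and depth must be >= 1")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error rate must lie in [0, 0.1]")


def simulate_selection(
    frequencies: dict[str, float],
    model: AffinityModel,
    cfg: SelectionSimConfig,
) -> tuple[VariantCounts, dict[str, VariantCounts]]:
    """Simulate phage-display selection rounds against each model target.

    Returns the sequenced input library counts and one output
    :class:`VariantCounts` per target. Selection multiplies proportions by
    the latent weight each round (proportional retention); only sequencing
    draws counts, multinomially at the configured depth.
    """
    peptides = sorted(frequencies)
    p0 = np.array([frequencies[p] for p in peptides], dtype=float)
    if not np.isclose(p0.sum(), 1.0):
        raise ValueError("input frequencies must sum to 1")
    rng = np.random.default_rng(cfg.seed)
    input_counts = VariantCounts(
        sample_id="input",
        counts=dict(zip(peptides, rng.multinomial(cfg.depth, p0).tolist())),
        n_reads_total=cfg.depth,
    )
    outputs = {}
    for target in model.targets:
        w = np.array([model.weight(p, target) for p in peptides])
        p = p0.copy()
        for _ in range(cfg.rounds):
            p = p * w
            p /= p.sum()
        outputs[target] = VariantCounts(
            sample_id=f"output_{target}",
            counts=dict(zip(peptides, rng.multinomial(cfg.depth, p).tolist())),
            n_reads_total=cfg.depth,
        )
    return input_counts, outputs


def synthesize_reads(
    counts: VariantCounts,
    oligo_map: dict[str, str],
    fwd_path: str | Path,
    rev_path: str | Path,
    scaffold: AmpliconScaffold | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> int:
    """Write a paired FASTQ emulating the amplicon construct, one pair per count.

    Each amplicon is fwd_demux + fwd_const + insert + rev_const +
    revcomp(rev_demux); the reverse mate is its reverse complement.
    Substitution errors are injected per base at ``error_rate``. Returns the
    number of read pairs written. Output is gzipped when the path ends in .gz.
    """
    scaffold = scaffold or AmpliconScaffold()
    missing = [p for p in counts.counts if p not in oligo_map]
    if missing:
        raise ValueError(f"no oligo for peptide(s): {missing[:5]}")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    def mutate(seq: str) -> str:
        if error_rate == 0:
            return seq
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
        for i in hits:
            choices = bases[bases != arr[i]]
            arr[i] = rng.choice(choices)
        return arr.tobytes().decode()

    def opener(path):
        path = Path(path)
        return gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")

    n_pairs = 0
    with opener(fwd_path) as fh_f, opener(rev_path) as fh_r:
        for peptide in sorted(counts.counts):
            insert = oligo_map[peptide]
            amplicon = (
                scaffold.fwd_demux + scaffold.fwd_const + insert
                + scaffold.rev_const + _revcomp(scaffold.rev_demux)
            )
            for _ in range(counts.counts[peptide]):
                rid = f"read{n_pairs:08d}"
                fwd = mutate(amplicon)
                rev = mutate(_revcomp(amplicon))
                fh_f.write(f"@{rid}\n{fwd}\n+\n{'I' * len(fwd)}\n")
                fh_r.write(f"@{rid}\n{rev}\n+\n{'I' * len(rev)}\n")
                n_pairs += 1
    return n_pairs


def oligo_map_for(peptides: list[str], model: CodonModel | None = None) -> dict[str, str]:
    """Deterministic insert (48-nt) per peptide via reverse translation."""
    model = model or CodonModel(mode="most_frequent")
    return {
        p: reverse_translate(PeptideVariant(p, frozenset(), "single"), model).insert_nt
        for p in peptides
    }


@dataclass(frozen=True)
class ChemotaxisSimConfig:
    b: float = -1.0
    c: float = 0.0
    d: float = 100.0
    e: float = 1e-8
    noise_sd: float = 5.0
    noise_model: str = "gaussian"  # or "negative_binomial"
    dispersion: float = 10.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def simulate_chemotaxis(cfg: ChemotaxisSimConfig, doses: np.ndarray) -> DoseResponseData:
    """Noisy log-logistic responses at the given molar doses, seeded."""
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(cfg.seed)
    x = np.repeat(doses, cfg.replicates)
    mean = ll3(x, cfg.b, cfg.c, cfg.d, cfg.e)
    if cfg.noise_model == "gaussian":
        y = mean + rng.normal(0.0, cfg.noise_sd, size=len(x))
        scale = "percent"
    elif cfg.noise_model == "negative_binomial":
        mu = np.maximum(mean, 1e-9)
        r = cfg.dispersion
        y = rng.negative_binomial(r, r / (r + mu)).astype(float)
        scale = "counts"
    else:
        raise ValueError(f"unknown noise model {cfg.noise_model!r}")
    return DoseResponseData(x, y, response_scale=scale)


def simulate_tpm(
    chemokines: list[str],
    profile: str = "lognormal",
    seed: int = 0,
    log_mean: float = 3.0,
    log_sd: float = 1.5,
) -> dict[str, float]:
    """Synthetic mean-TPM table emulating chemokine expression in bulk RNA-seq.

    Profiles: ``uniform`` (equal TPM), ``lognormal`` (skewed, as real
    chemokine panels are), ``sparse`` (one dominant chemokine).
    """
    if not chemokines:
        raise ValueError("chemokine list must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(chemokines)
    if profile == "uniform":
        vals = np.full(n, 100.0)
    elif profile == "lognormal":
        vals = rng.lognormal(log_mean, log_sd, size=n)
    elif profile == "sparse":
        vals = rng.lognormal(log_mean - 2.0, 0.5, size=n)
        vals[rng.integers(n)] = 10 * vals.sum()
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return dict(zip(chemokines, vals.tolist()))


def make_toy_complex(
    out_prefix: str | Path,
    n_site: int = 7,
    n_blocked: int = 3,
    n_chemokine_res: int = 12,
    spacing: float = 20.0,
    contact_distance: float = 4.5,
) -> tuple[Path, Path]:
    """Write a three-chain toy model (mmCIF + PDB) with prescribed contacts.

    Chain A is a chemokine-like chain of single-CA glycines spread along x
    far enough apart that no accidental contacts form; chain B (partner)
    places one residue ``contact_distance`` from each of the first
    ``n_site`` A residues; chain C (peptide) covers the first ``n_blocked``
    site residues from the opposite side. Under the 5 Å rule the A:B
    binding site has exactly ``n_site`` residues of which ``n_blocked``
    are also within range of the peptide.
    """
    if not 0 <= n_blocked <= n_site <= n_chemokine_res:
        raise ValueError("need 0 <= n_blocked <= n_site <= n_chemokine_res")
    if contact_distance >= 5.0 or spacing <= 2 * 5.0:
        raise ValueError("infeasible geometry for the 5 Å contact rule")
    st = gemmi.Structure()
    st.name = "toy_complex"
    model = gemmi.Model("1")

    def add_chain(name: str, positions: list[tuple[float, float, float]]) -> None:
        chain = gemmi.Chain(name)
        for i, (x, y, z) in enumerate(positions, start=1):
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)

    chemokine = [(i * spacing, 0.0, 0.0) for i in range(n_chemokine_res)]
    partner = [(i * spacing, contact_distance, 0.0) for i in range(n_site)]
    if n_blocked:
        peptide = [(i * spacing, -contact_distance, 0.0) for i in range(n_blocked)]
    else:  # keep the chain present but out of range of everything
        peptide = [(0.0, -10.0 * spacing, 0.0)]
    add_chain("A", chemokine)
    add_chain("B", partner)
    add_chain("C", peptide)
    st.add_model(model)
    st.setup_entities()
    out_prefix = Path(out_prefix)
    cif_path = out_prefix.with_suffix(".cif")
    pdb_path = out_prefix.with_suffix(".pdb")
    doc = st.make_mmcif_document()
    doc.write_file(str(cif_path))
    st.write_pdb(str(pdb_path))
    return cif_path, pdb_path
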