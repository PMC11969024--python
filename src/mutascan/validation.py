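"""Simulation-based validation studies bundled with the package.

These run the full pipeline on simulator output with known ground truth and
report recovery metrics: how reliably the selection stage finds the truly
improving mutations, and how accurately dose-response fitting recovers
potency from noisy replicate data.
"""

from __future__ import annotations

import numpy as np

from .design import SYNTHETIC_PARENT, build_nnk_library
from .doseresponse import DoseResponseData, fit_ll3, to_potency
from .enrichment import Target, TargetPanel, build_enrichment, compute_delta, compute_frequencies
from .selection import (
    Mutation,
    SelectionConfig,
    select_improving_mutations,
    summarize_mutation_effects,
)
from .simulate import AffinityModel, ChemotaxisSimConfig, SelectionSimConfig, simulate_chemotaxis, simulate_selection


def default_panel(with_control: bool = True) -> TargetPanel:
    """A six-chemokine panel (3 CC, 3 CXnC), optionally with the control."""
    targets = [
        Target("CCL2", "CC", "inflammatory"),
        Target("CCL5", "CC", "inflammatory"),
        Target("CCL8", "CC", "dual"),
        Target("CXCL10", "CXnC", "inflammatory"),
        Target("CXCL11", "CXnC", "dual"),
        Target("CXCL12", "CXnC", "homeostatic"),
    ]
    if with_control:
        targets.append(Target("C5A", None, None, is_control=True))
    return TargetPanel(targets)


def improving_mutation_truth(
    parent: str = SYNTHETIC_PARENT, n_improving: int = 12, seed: int = 0
) -> list[Mutation]:
    """A reproducible set of truly improving mutations at distinct positions."""
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(parent), size=n_improving, replace=False) + 1
    muts = []
    for pos in sorted(positions.tolist()):
        from_aa = parent[pos - 1]
        to_aa = "W" if from_aa != "W" else "F"
        muts.append(Mutation(pos, from_aa, to_aa))
    return muts


def improving_mutation_recovery(
    seed: int = 0,
    depth: int = 100_000,
    rounds: int = 3,
    min_effect: float = 1.0,
    max_effect: float = 2.0,
    n_improving: int = 12,
) -> dict:
    """End-to-end recovery of improving mutations from a simulated screen.

    An NNK single-mutant library of the synthetic parent is put through the
    selection simulator: the true improving mutations carry additive log2
    selection-weight effects of at least ``min_effect`` on every panel
    chemokine, all other mutations are neutral. The counts then flow through
    the enrichment stage (minimum-proportion imputation, as for a sparse
    single-mutant library) and the two-pronged mean/peak selection; recovery
    is the fraction of true improving mutations present in the selected set.
    """
    rng = np.random.default_rng(seed)
    parent = SYNTHETIC_PARENT
    panel = default_panel(with_control=False)
    truth = improving_mutation_truth(parent, n_improving, seed=seed)
    effects = {}
    for mut in truth:
        for target in panel.names("ALL"):
            effects[(mut, target)] = float(rng.uniform(min_effect, max_effect))
    model = AffinityModel(parent, panel.names("ALL"), effects=effects)
    library = [v.sequence for v in build_nnk_library(parent)]
    freqs = {p: 1.0 / len(library) for p in library}
    cfg = SelectionSimConfig(rounds=rounds, depth=depth, seed=int(rng.integers(2**31)))
    input_counts, outputs = simulate_selection(freqs, model, cfg)
    lib = set(library)
    ft_in = compute_frequencies(input_counts, lib, "impute_min")
    fts_out = {t: compute_frequencies(vc, lib, "impute_min") for t, vc in outputs.items()}
    tbl = compute_delta(build_enrichment(ft_in, fts_out), parent)
    effects_cc = summarize_mutation_effects(tbl, panel, parent, "CC")
    effects_cxnc = summarize_mutation_effects(tbl, panel, parent, "CXnC")
    selected = select_improving_mutations(effects_cc, effects_cxnc, SelectionConfig())
    recovered = set(selected) & set(truth)
    return {
        "truth": truth,
        "selected": selected,
        "recovery": len(recovered) / len(truth),
        "table": tbl,
    }


def pic50_recovery_rate(
    n_runs: int = 100,
    noise_sd: float = 5.0,
    replicates: int = 3,
    tolerance_log: float = 0.1,
    seed: int = 0,
) -> dict:
    """Fraction of noisy inhibition fits whose pIC50 lands within tolerance.

    Each run simulates an inhibitor dose-response (log-logistic, upper
    asymptote 100%, Gaussian replicate noise) at a randomly drawn true IC50
    and refits it; success is |pIC50_hat - pIC50_true| <= ``tolerance_log``.
    """
    rng = np.random.default_rng(seed)
    doses = np.logspace(-9.5, -5.5, 8)
    hits, errors = 0, []
    for _ in range(n_runs):
        true_e = float(10 ** rng.uniform(-8.0, -6.5))
        cfg = ChemotaxisSimConfig(
            b=1.0, c=0.0, d=100.0, e=true_e,
            noise_sd=noise_sd, replicates=replicates,
            seed=int(rng.integers(2**31)),
        )
        data = simulate_chemotaxis(cfg, doses)
        fit = fit_ll3(DoseResponseData(data.doses, data.responses), mode="IC")
        err = to_potency(fit.e) - to_potency(true_e)
        errors.append(err)
        if abs(err) <= tolerance_log:
            hits += 1
    return {
        "rate": hits / n_runs,
        "median_bias": float(np.median(errors)),
        "n_runs": n_runs,
    }
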