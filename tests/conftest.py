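import numpy as np
import pytest

from mutascan import (
    AffinityModel,
    Mutation,
    SelectionSimConfig,
    SYNTHETIC_PARENT,
    Target,
    TargetPanel,
    apply_mutations,
    build_enrichment,
    compute_delta,
    compute_frequencies,
    simulate_selection,
)


@pytest.fixture(scope="session")
def parent() -> str:
    return SYNTHETIC_PARENT


@pytest.fixture(scope="session")
def panel() -> TargetPanel:
    """Six chemokine targets (3 CC, 3 CXnC) plus a non-specific control."""
    targets = [
        Target("CCL2", "CC", "inflammatory"),
        Target("CCL5", "CC", "inflammatory"),
        Target("CCL8", "CC", "dual"),
        Target("CXCL10", "CXnC", "inflammatory"),
        Target("CXCL11", "CXnC", "dual"),
        Target("CXCL12", "CXnC", "homeostatic"),
        Target("C5A", None, None, is_control=True),
    ]
    return TargetPanel(targets)


def run_selection_pipeline(library, model, cfg, parent, mode="add_one"):
    """Simulate selection and push the counts through the enrichment stage."""
    freqs = {p: 1.0 / len(library) for p in library}
    input_counts, outputs = simulate_selection(freqs, model, cfg)
    lib = set(library)
    ft_in = compute_frequencies(input_counts, lib, mode)
    fts_out = {t: compute_frequencies(vc, lib, mode) for t, vc in outputs.items()}
    return compute_delta(build_enrichment(ft_in, fts_out), parent)


@pytest.fixture(scope="session")
def two_variant_run(parent):
    """Parent plus one 2x-advantaged variant, three selection rounds."""
    mut = Mutation(5, "Y", "W")
    var = apply_mutations(parent, {mut})
    model = AffinityModel(parent, ["T1"], effects={(mut, "T1"): 1.0})
    cfg = SelectionSimConfig(rounds=3, depth=100_000, seed=11)
    tbl = run_selection_pipeline([parent, var], model, cfg, parent)
    return tbl, var
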