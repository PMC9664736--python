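import pytest

from consplice import simulate_bundle
from consplice.pipeline import fit_from_bundle, prepare_model_inputs


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic bundle shared by read-only tests."""
    return simulate_bundle(seed=11)


@pytest.fixture(scope="session")
def small_bundle():
    """A lighter bundle for tests that refit models."""
    from consplice import SimulationConfig

    return simulate_bundle(SimulationConfig(seed=11, n_genes=14, n_pathogenic=40, n_benign=160))


@pytest.fixture(scope="session")
def fitted_model(bundle):
    model, _ = fit_from_bundle(bundle)
    return model


@pytest.fixture(scope="session")
def model_inputs(bundle):
    """Filtered variants + site index for the default bundle."""
    from consplice.io import CoverageTable, ExclusionMask
    import pandas as pd

    qual = bundle.mask_records[bundle.mask_records["identity"] >= 0.95]
    intervals = {}
    for row in qual.itertuples(index=False):
        intervals.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
    mask = ExclusionMask(intervals=intervals)
    frames = {
        str(chrom): pd.Series(
            sub["fraction_10x"].to_numpy(), index=sub["pos"].to_numpy("int64") - 1
        )
        for chrom, sub in bundle.coverage_records.groupby("chrom")
    }
    coverage = CoverageTable(frames=frames)
    data, tally = prepare_model_inputs(
        bundle.genes, bundle.scores, bundle.variants, bundle.genome,
        mask=mask, coverage=coverage, truth=bundle.truth, reference=bundle.reference,
    )
    return data, tally
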