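"""End-to-end convenience wrappers over filtering, site selection, and fitting."""

from __future__ import annotations

import pandas as pd

from .constraint import SplicingConstraintModel
from .genome import GeneModel, GenomeConfig
from .io import (
    CoverageTable,
    ExclusionMask,
    filter_population_variants,
    select_model_sites,
)
from .substitution import SiteScoreTable


def prepare_model_inputs(
    genes: list[GeneModel],
    scores: SiteScoreTable,
    variants: pd.DataFrame,
    genome: GenomeConfig,
    mask: ExclusionMask | None = None,
    coverage: CoverageTable | None = None,
    truth: pd.DataFrame | None = None,
    reference=None,
) -> tuple[dict, dict[str, int]]:
    """Filter the population callset, select model sites, and package fit inputs."""
    retained, tally = filter_population_variants(
        variants, genes, scores, mask=mask, coverage=coverage, truth=truth,
        reference=reference,
    )
    site_index = select_model_sites(scores, genes, genome, mask=mask, coverage=coverage)
    data = {
        "genes": genes,
        "scores": scores,
        "variants": retained,
        "genome": genome,
        "site_index": site_index,
    }
    return data, tally


def fit_constraint_model(
    genes,
    scores,
    variants,
    genome,
    mask=None,
    coverage=None,
    truth=None,
    reference=None,
    **model_params,
) -> tuple[SplicingConstraintModel, dict[str, int]]:
    data, tally = prepare_model_inputs(
        genes, scores, variants, genome, mask=mask, coverage=coverage,
        truth=truth, reference=reference,
    )
    model = SplicingConstraintModel(**model_params).fit(data)
    return model, tally


def fit_from_bundle(bundle, use_mask: bool = True, use_coverage: bool = True, **model_params):
    """Fit the constraint model directly from a synthetic bundle."""
    from .io import ExclusionMask, CoverageTable
    import numpy as np

    mask = None
    if use_mask and len(bundle.mask_records):
        qual = bundle.mask_records[bundle.mask_records["identity"] >= 0.95]
        intervals: dict[str, list[tuple[int, int]]] = {}
        for row in qual.itertuples(index=False):
            intervals.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
        mask = ExclusionMask(intervals=intervals)
    coverage = None
    if use_coverage:
        frames = {
            str(chrom): pd.Series(
                sub["fraction_10x"].to_numpy(),
                index=sub["pos"].to_numpy(dtype="int64") - 1,
            )
            for chrom, sub in bundle.coverage_records.groupby("chrom")
        }
        coverage = CoverageTable(frames=frames)
    return fit_constraint_model(
        bundle.genes,
        bundle.scores,
        bundle.variants,
        bundle.genome,
        mask=mask,
        coverage=coverage,
        truth=bundle.truth,
        reference=bundle.reference,
        **model_params,
    )
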