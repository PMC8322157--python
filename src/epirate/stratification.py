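"""Annotation-, shape- and chromosome-zone-stratified rate estimation.

Regions are labelled by their overlap with genomic features (genes, TEs,
UTRs, promoters), with gene labels split into gene-body-methylated (gbM)
and non-gbM genes from an external classification; regions matching no
feature are intergenic.  CG regions are further classed by shape (duplet vs
multiplet, dense vs sparse, short vs long) and assigned to a chromosome zone
(arm / pericentromere / centromere) by their midpoint.  Any such labelling
can then drive per-stratum divergence tables and model fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .divergence import Pedigree, divergence_table, state_frequencies
from .rate_models import RateFit, compare_models, fit_all_models
from .segmentation import Region

FEATURE_LABELS = (
    "gene",
    "gbM_gene",
    "non_gbM_gene",
    "TE",
    "promoter",
    "UTR5",
    "UTR3",
    "intergenic",
)
ZONES = ("arm", "pericentromere", "centromere")

DEFAULT_MIN_OVERLAP = 0.4
PROMOTER_LENGTH = 1500

#: Genome-wide medians of CG region density and span used for shape classes.
DEFAULT_DENSITY_MEDIAN = 0.105
DEFAULT_SIZE_MEDIAN = 104


def _build_trees(features: pd.DataFrame) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in features.itertuples(index=False):
        key = (row.chrom, row.feature)
        if row.end > row.start:
            trees.setdefault(key, IntervalTree()).addi(row.start, row.end, getattr(row, "name", None))
    return trees


def assign_features(
    regions: list[Region],
    features: pd.DataFrame,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Label regions by feature overlap (region-relative fraction).

    ``features`` has columns chrom, start, end, feature (and optionally
    name); a region receives a feature label when the overlap covers at
    least ``min_overlap_frac`` of the region span.  Regions with no feature
    label are intergenic.  Returns a boolean DataFrame indexed by region id
    with one column per feature type plus ``intergenic``.
    """
    feat_chroms = set(features["chrom"])
    region_chroms = {r.chrom for r in regions}
    unknown = region_chroms - feat_chroms
    if unknown and not region_chroms & feat_chroms:
        raise ValueError(
            f"annotation chromosomes {sorted(feat_chroms)} share nothing with "
            f"region chromosomes {sorted(unknown)}"
        )
    types = sorted(set(features["feature"]))
    trees = _build_trees(features)
    out = pd.DataFrame(
        False,
        index=pd.Index([r.region_id for r in regions], name="region_id"),
        columns=types + ["intergenic"],
    )
    for r in regions:
        hit_any = False
        for t in types:
            tree = trees.get((r.chrom, t))
            if tree is None:
                continue
            ov = sum(
                min(iv.end, r.end) - max(iv.begin, r.start)
                for iv in tree.overlap(r.start, r.end)
            )
            if ov / r.span >= min_overlap_frac:
                out.loc[r.region_id, t] = True
                hit_any = True
        if not hit_any:
            out.loc[r.region_id, "intergenic"] = True
    return out


def make_promoters(
    genes: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    length: int = PROMOTER_LENGTH,
) -> pd.DataFrame:
    """Promoter intervals: ``length`` bp upstream of each TSS, strand-aware,
    clamped to chromosome bounds.  ``genes`` needs chrom, start, end, strand.
    """
    rows = []
    for g in genes.itertuples(index=False):
        if g.strand == "+":
            start, end = g.start - length, g.start
        else:
            start, end = g.end, g.end + length
        start = max(start, 0)
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[g.chrom])
        if end > start:
            rows.append((g.chrom, start, end, "promoter", getattr(g, "name", None)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "feature", "name"])


def split_gbM(
    regions: list[Region],
    labels: pd.DataFrame,
    genes: pd.DataFrame,
    gbm_ids: set[str],
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Split the gene label into gbM_gene / non_gbM_gene by overlap with the
    listed gene models.  A region over both kinds gets both labels."""
    known = set(genes["name"])
    stray = gbm_ids - known
    if stray:
        warnings.warn(
            f"{len(stray)} gbM ids absent from the gene annotation", stacklevel=2
        )
    gb = genes[genes["name"].isin(gbm_ids)].assign(feature="gbM_gene")
    non = genes[~genes["name"].isin(gbm_ids)].assign(feature="non_gbM_gene")
    sub = assign_features(regions, pd.concat([gb, non]), min_overlap_frac)
    out = labels.copy()
    for col in ("gbM_gene", "non_gbM_gene"):
        got = sub[col] if col in sub.columns else False
        out[col] = (got & labels.get("gene", True)) if "gene" in labels else got
    return out


def classify_shape(
    regions: list[Region],
    density_median: float | None = DEFAULT_DENSITY_MEDIAN,
    size_median: float | None = DEFAULT_SIZE_MEDIAN,
) -> pd.DataFrame:
    """Size/density classes for CG regions.

    A duplet is a single strand-symmetric CG pair (two cytosines); other
    regions are multiplets, classed dense/sparse against the density median
    and short/long against the span median (values equal to a median go to
    the lower class).  Pass ``None`` for either median to recompute it from
    the multiplets at hand.
    """
    for r in regions:
        if r.context != "CG":
            raise ValueError(f"shape classes are defined for CG regions, got {r.context}")
    ids = pd.Index([r.region_id for r in regions], name="region_id")
    n_c = np.array([r.n_c for r in regions])
    span = np.array([r.span for r in regions])
    dens = np.array([r.density for r in regions])
    is_duplet = (n_c == 2)
    multi = ~is_duplet
    if density_median is None:
        density_median = float(np.median(dens[multi]))
    if size_median is None:
        size_median = float(np.median(span[multi]))
    size_class = np.where(
        is_duplet,
        "duplet",
        np.where(span <= size_median, "multiplet_short", "multiplet_long"),
    )
    density_class = np.where(
        multi, np.where(dens > density_median, "dense", "sparse"), "NA"
    )
    return pd.DataFrame(
        {"size_class": size_class, "density_class": density_class}, index=ids
    )


def assign_zone(regions: list[Region], partition: pd.DataFrame) -> pd.Series:
    """Chromosome zone of each region midpoint.

    ``partition`` has columns chrom, start, end, zone and must tile each
    region-bearing chromosome; a midpoint falling in a gap is an error.
    """
    bad = set(partition["zone"]) - set(ZONES)
    if bad:
        raise ValueError(f"unknown zones in partition: {sorted(bad)}")
    by_chrom: dict[str, IntervalTree] = {}
    for row in partition.itertuples(index=False):
        by_chrom.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.zone)
    zones = []
    for r in regions:
        tree = by_chrom.get(r.chrom)
        if tree is None:
            raise ValueError(f"partition missing chromosome {r.chrom!r}")
        mid = (r.start + r.end) // 2
        hits = tree.at(mid)
        if not hits:
            raise ValueError(f"partition gap at {r.chrom}:{mid}")
        zones.append(next(iter(hits)).data)
    return pd.Series(
        zones, index=pd.Index([r.region_id for r in regions], name="region_id"),
        name="zone",
    )


@dataclass
class StratumFit:
    """Per-stratum divergence table and model fits."""

    name: str
    n_regions: int
    records: pd.DataFrame | None
    fits: dict[str, RateFit] | None
    comparison: dict | None
    stable: bool


def stratified_rates(
    strata: dict[str, pd.Index],
    status: pd.DataFrame,
    retained: pd.Series,
    pedigree: Pedigree,
    min_regions: int = 50,
    restarts: int = 10,
    seed: int = 0,
    n_bootstrap: int = 0,
    kinds: tuple[str, ...] = ("ABneutral", "ABnull", "ABmm", "ABuu"),
) -> dict[str, StratumFit]:
    """Divergence tables and model fits per stratum of retained regions.

    ``strata`` maps stratum name to region-id sets (crossed strata are just
    intersected id sets).  Strata below ``min_regions`` retained regions are
    flagged unstable; empty strata are skipped with a warning.
    """
    kept = retained[retained].index
    out: dict[str, StratumFit] = {}
    for name, ids in strata.items():
        ids = pd.Index(ids).intersection(kept)
        if len(ids) == 0:
            warnings.warn(f"stratum {name!r} empty after filters; skipped", stacklevel=2)
            out[name] = StratumFit(name, 0, None, None, None, False)
            continue
        stable = len(ids) >= min_regions
        if not stable:
            warnings.warn(
                f"stratum {name!r} has only {len(ids)} regions; estimates "
                "will be noisy",
                stacklevel=2,
            )
        records = divergence_table(pedigree, status.loc[ids])
        freqs = state_frequencies(status.loc[ids])
        fits = fit_all_models(
            records,
            restarts=restarts,
            seed=seed,
            n_bootstrap=n_bootstrap,
            kinds=kinds,
            observed_meth_fraction=float(freqs[2]),
        )
        comparison = compare_models(fits) if set(kinds) == set(("ABneutral", "ABnull", "ABmm", "ABuu")) else None
        out[name] = StratumFit(name, len(ids), records, fits, comparison, stable)
    return out
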