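"""End-to-end orchestration: segmentation -> calling -> divergence -> rates.

One :class:`PipelineConfig` drives the whole analysis; every stage persists
its artifact (regions BED, calls TSV, divergence TSV, fit JSON) plus a
resolved-config copy and a machine-readable log of stage-wise region counts,
so a run is reproducible and auditable.  Thresholds default to the standard
analysis values: 185 bp span cap, 100 bp bins, mean coverage > 3 reads per
cytosine, posterior >= 0.99, 40% annotation overlap, 1.5 kb promoters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .divergence import divergence_table, pair_weight_matrix, state_frequencies
from .rate_models import compare_models, fit_all_models, region_bootstrap
from .segmentation import (
    DEFAULT_MAX_SPAN,
    Region,
    build_seeds,
    merge_regions,
    regions_to_frame,
    scan_cytosines,
)
from .status_calling import (
    aggregate_counts,
    call_status,
    calls_to_frame,
    coverage_filter,
    fit_status_model,
)

logger = logging.getLogger("epirate")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for one pipeline run."""

    fasta: str
    counts: str
    pedigree: str
    out_dir: str
    contexts: list[str] = field(default_factory=lambda: ["CG"])
    annotation: str | None = None
    gbm_list: str | None = None
    zones: str | None = None
    chromosomes: list[str] | None = None  # nuclear whitelist; None = all
    max_span: int = DEFAULT_MAX_SPAN
    bin_width: int = 100
    min_mean_coverage: float = 3.0
    posterior_min: float = 0.99
    min_overlap_frac: float = 0.4
    promoter_length: int = 1500
    restarts: int = 20
    n_bootstrap: int = 200
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


def fill_region_sites(
    regions: list[Region], sequences: dict[str, str], context: str
) -> list[Region]:
    """Recover member cytosine positions for regions read from BED by
    re-scanning the genome for context cytosines within each span."""
    sites = scan_cytosines(sequences, context)
    by_chrom: dict[str, np.ndarray] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s.pos)  # type: ignore[arg-type]
    by_chrom = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}
    out = []
    for r in regions:
        pos = by_chrom.get(r.chrom, np.empty(0, dtype=int))
        lo = np.searchsorted(pos, r.start, side="left")
        hi = np.searchsorted(pos, r.end, side="left")
        out.append(Region(r.chrom, r.start, r.end, context, [int(p) for p in pos[lo:hi]]))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and persist artifacts under ``config.out_dir``.

    Returns a bundle dict with the in-memory results and the path of every
    artifact written.  Reruns with identical config and inputs reproduce
    identical outputs (all randomness is seeded from ``config.seed``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    log: dict = {"stages": {}}

    for path, label in (
        (config.fasta, "fasta"),
        (config.counts, "counts"),
        (config.pedigree, "pedigree"),
    ):
        if not Path(path).exists():
            raise FileNotFoundError(f"{label} input not found: {path}")

    sequences = eio.read_fasta(config.fasta)
    if config.chromosomes is not None:
        sequences = {c: s for c, s in sequences.items() if c in config.chromosomes}
        if not sequences:
            raise ValueError("chromosome whitelist removed every sequence")
    counts_df = eio.read_counts_tsv(config.counts)
    pedigree = eio.read_pedigree_yaml(config.pedigree)
    samples = pedigree.sequenced_samples

    bundle: dict = {"config": config, "pedigree": pedigree, "contexts": {}}
    for context in config.contexts:
        ctx_log: dict = {}
        try:
            sites = scan_cytosines(sequences, context)
            regions = merge_regions(build_seeds(sites, context), config.max_span, context)
        except Exception as exc:
            raise RuntimeError(f"segmentation failed ({context}): {exc}") from exc
        ctx_log["n_sites"] = len(sites)
        ctx_log["n_regions"] = len(regions)
        eio.write_regions_bed(regions, out / f"regions_{context}.bed")
        regions_to_frame(regions).to_csv(
            out / f"regions_{context}.tsv", sep="\t", index=False
        )

        ctx_counts = counts_df[counts_df["context"] == context]
        rcm = aggregate_counts(ctx_counts, regions, samples)
        cov_mask = coverage_filter(rcm, samples, config.min_mean_coverage)
        ctx_log["n_pass_coverage"] = int(cov_mask.sum())
        ctx_log["retention_coverage"] = float(cov_mask.mean()) if len(cov_mask) else 0.0

        passing = rcm.meth.index[cov_mask]
        model = fit_status_model(
            rcm.meth.loc[passing].to_numpy(), rcm.total.loc[passing].to_numpy()
        )
        calls = call_status(rcm, model, config.posterior_min, cov_mask)
        ctx_log["n_retained"] = int(calls.retained.sum())
        ctx_log["retention_final"] = (
            float(calls.retained.sum() / len(cov_mask)) if len(cov_mask) else 0.0
        )
        calls_to_frame(calls).to_csv(out / f"calls_{context}.tsv", sep="\t", index=False)

        records = divergence_table(pedigree, calls.status, calls.retained, context)
        records.to_csv(out / f"divergence_{context}.tsv", sep="\t", index=False)

        freqs = state_frequencies(calls.status, calls.retained)
        ctx_log["state_frequencies"] = {
            "U": float(freqs[0]), "I": float(freqs[1]), "M": float(freqs[2])
        }
        fits = fit_all_models(
            records,
            restarts=config.restarts,
            seed=config.seed,
            n_bootstrap=0,
            observed_meth_fraction=float(freqs[2]),
        )
        if config.n_bootstrap > 0:
            ti, tj, W, m_frac = pair_weight_matrix(
                pedigree, calls.status, calls.retained
            )
            for f in fits.values():
                if f.kind != "ABnull":
                    region_bootstrap(
                        f, ti, tj, W, m_frac, config.n_bootstrap, seed=config.seed
                    )
        comparison = compare_models(fits)
        fit_report = {
            "context": context,
            "models": {k: f.to_dict() for k, f in fits.items()},
            "comparison": comparison,
        }
        with open(out / f"fits_{context}.json", "w") as fh:
            json.dump(fit_report, fh, indent=2)
        bundle["contexts"][context] = {
            "regions": regions,
            "counts": rcm,
            "calls": calls,
            "records": records,
            "fits": fits,
            "comparison": comparison,
        }
        log["stages"][context] = ctx_log
        logger.info("context %s: %s", context, ctx_log)

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    bundle["log"] = log
    return bundle
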