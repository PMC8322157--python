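"""Region-level methylation status calling from bisulfite read counts.

Per-cytosine methylated/total read counts are summed over each region's
member cytosines, regions with thin coverage are filtered out, and each
region is classified per sample as unmethylated (U), intermediate (I) or
methylated (M) by maximum posterior probability under a three-component
binomial mixture fitted by EM.  The intermediate class captures heterozygous
epigenotypes (one methylated and one unmethylated epiallele) as well as
genuinely mosaic regions.

Two filters gate the downstream divergence analysis, both applied across
every sequenced individual of a pedigree: mean coverage strictly above three
reads per cytosine, and a classification posterior of at least 0.99.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .segmentation import Region

STATUSES = ("U", "I", "M")

DEFAULT_MIN_MEAN_READS = 3.0
DEFAULT_POSTERIOR_MIN = 0.99

#: EM initialisation: success probabilities for the U/I/M components.
INIT_P = (0.01, 0.5, 0.95)


@dataclass
class RegionCountMatrix:
    """Methylated and total read counts per region per sample.

    ``meth`` and ``total`` are integer DataFrames indexed by region id with
    one column per sample; ``n_c`` gives each region's member-cytosine count.
    """

    meth: pd.DataFrame
    total: pd.DataFrame
    n_c: pd.Series

    def __post_init__(self) -> None:
        if (self.meth.to_numpy() > self.total.to_numpy()).any():
            raise ValueError("methylated read count exceeds total read count")

    @property
    def region_ids(self) -> pd.Index:
        return self.meth.index

    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)


@dataclass
class BinomialMixture:
    """A 3-component binomial mixture with components ordered U < I < M."""

    p: np.ndarray
    weights: np.ndarray
    converged: bool = True
    n_iter: int = 0
    log_likelihood: float = float("nan")


@dataclass
class StatusCallSet:
    """Per region-sample status calls plus the all-samples retention mask.

    ``status`` and ``posterior`` are DataFrames (region x sample); ``retained``
    marks regions whose maximum posterior reaches the threshold in every
    sample.
    """

    status: pd.DataFrame
    posterior: pd.DataFrame
    level: pd.DataFrame
    retained: pd.Series
    posterior_min: float = DEFAULT_POSTERIOR_MIN


def aggregate_counts(
    cytosine_counts: pd.DataFrame,
    regions: list[Region],
    samples: list[str] | None = None,
) -> RegionCountMatrix:
    """Sum per-cytosine counts over each region's member cytosines.

    ``cytosine_counts`` carries columns chrom, pos (0-based), strand, context
    and per-sample count columns ``meth_<sample>`` / ``total_<sample>``.
    Cytosines absent from the table contribute 0/0; count records at
    positions that are not member cytosines of any region raise a warning
    and are reported as unassigned.
    """
    if samples is None:
        samples = sorted(
            c[len("meth_"):] for c in cytosine_counts.columns if c.startswith("meth_")
        )
    if not samples:
        raise ValueError("no per-sample count columns found")
    for s in samples:
        bad = cytosine_counts[f"meth_{s}"] > cytosine_counts[f"total_{s}"]
        if bad.any():
            row = cytosine_counts[bad].iloc[0]
            raise ValueError(
                f"meth > total for sample {s} at {row['chrom']}:{row['pos']}"
            )

    site_to_region: dict[tuple[str, int], int] = {}
    for i, r in enumerate(regions):
        for p in r.sites:
            site_to_region[(r.chrom, p)] = i

    n = len(regions)
    meth = np.zeros((n, len(samples)), dtype=np.int64)
    total = np.zeros((n, len(samples)), dtype=np.int64)
    keys = list(zip(cytosine_counts["chrom"], cytosine_counts["pos"]))
    ridx = np.array([site_to_region.get(k, -1) for k in keys])
    n_unassigned = int((ridx == -1).sum())
    if n_unassigned:
        warnings.warn(
            f"{n_unassigned} count records map to no region and were ignored",
            stacklevel=2,
        )
    ok = ridx >= 0
    for j, s in enumerate(samples):
        np.add.at(meth[:, j], ridx[ok], cytosine_counts[f"meth_{s}"].to_numpy()[ok])
        np.add.at(total[:, j], ridx[ok], cytosine_counts[f"total_{s}"].to_numpy()[ok])
    ids = pd.Index([r.region_id for r in regions], name="region_id")
    return RegionCountMatrix(
        meth=pd.DataFrame(meth, index=ids, columns=samples),
        total=pd.DataFrame(total, index=ids, columns=samples),
        n_c=pd.Series([r.n_c for r in regions], index=ids),
    )


def coverage_filter(
    counts: RegionCountMatrix,
    samples: list[str] | None = None,
    min_mean_reads_per_c: float = DEFAULT_MIN_MEAN_READS,
) -> pd.Series:
    """Mask of regions with mean coverage strictly above the threshold in
    every sample; regions with no member cytosines fail automatically."""
    if samples is None:
        samples = counts.samples
    missing = set(samples) - set(counts.samples)
    if missing:
        raise ValueError(f"count matrix lacks sequenced samples: {sorted(missing)}")
    n_c = counts.n_c.to_numpy().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_cov = counts.total[samples].to_numpy() / n_c[:, None]
    ok = np.where(n_c[:, None] > 0, mean_cov > min_mean_reads_per_c, False)
    return pd.Series(ok.all(axis=1), index=counts.region_ids, name="pass_coverage")


def _binom_logpmf(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )


def fit_status_model(
    meth: np.ndarray,
    total: np.ndarray,
    init_p: tuple[float, float, float] = INIT_P,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> BinomialMixture:
    """Fit the 3-component binomial mixture by expectation-maximisation.

    Observations with zero total reads are ignored.  Components are
    relabelled by ascending success probability so that index 0/1/2 always
    means U/I/M.  If a component's weight collapses the fit falls back to
    the fixed initialisation with a warning.
    """
    meth = np.asarray(meth, dtype=float).ravel()
    total = np.asarray(total, dtype=float).ravel()
    use = total > 0
    meth, total = meth[use], total[use]
    if meth.size < 100:
        raise ValueError(f"need >= 100 observations with coverage, got {meth.size}")
    p = np.array(init_p, dtype=float)
    w = np.full(3, 1 / 3)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = np.stack([_binom_logpmf(meth, total, pk) for pk in p], axis=1)
        logp += np.log(w)
        norm = logsumexp(logp, axis=1)
        resp = np.exp(logp - norm[:, None])
        ll = float(norm.sum())
        w_new = resp.mean(axis=0)
        if (w_new < 1e-10).any():
            warnings.warn(
                "EM degenerated (component weight -> 0); falling back to "
                "fixed initialisation parameters",
                stacklevel=2,
            )
            return BinomialMixture(
                np.array(init_p), np.full(3, 1 / 3), converged=False, n_iter=it
            )
        denom = resp.T @ total
        p = (resp.T @ meth) / denom
        w = w_new
        if ll - ll_prev < tol and it > 1:
            converged = True
            break
        ll_prev = ll
    order = np.argsort(p)
    return BinomialMixture(p[order], w[order], converged, it, ll)


def posterior_probs(
    meth: np.ndarray, total: np.ndarray, model: BinomialMixture
) -> np.ndarray:
    """Posterior over (U, I, M) for each observation; rows sum to one."""
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    logp = np.stack(
        [_binom_logpmf(meth, total, pk) for pk in model.p], axis=-1
    ) + np.log(model.weights)
    return np.exp(logp - logsumexp(logp, axis=-1, keepdims=True))


def call_status(
    counts: RegionCountMatrix,
    model: BinomialMixture,
    posterior_min: float = DEFAULT_POSTERIOR_MIN,
    region_mask: pd.Series | None = None,
) -> StatusCallSet:
    """Classify each region-sample by maximum posterior and build the
    all-samples retention mask.

    Argmax ties are broken toward I (the middle class), which contributes
    at most 0.5 to any pairwise divergence.
    """
    ids = counts.region_ids
    if region_mask is not None:
        ids = ids[region_mask.reindex(ids).fillna(False).to_numpy(dtype=bool)]
    meth = counts.meth.loc[ids].to_numpy(dtype=float)
    total = counts.total.loc[ids].to_numpy(dtype=float)
    assert (total > 0).all(), "coverage filter must precede status calling"
    post = posterior_probs(meth, total, model)  # (regions, samples, 3)
    max_post = post.max(axis=2)
    # argmax with ties toward I: boost I by an epsilon below resolution
    tie_pref = np.array([0.0, 1e-12, 0.0])
    status_idx = (post + tie_pref).argmax(axis=2)
    status = np.array(STATUSES)[status_idx]
    with np.errstate(invalid="ignore"):
        level = meth / total
    retained = pd.Series(
        (max_post >= posterior_min).all(axis=1), index=ids, name="pass_posterior"
    )
    cols = counts.samples
    return StatusCallSet(
        status=pd.DataFrame(status, index=ids, columns=cols),
        posterior=pd.DataFrame(max_post, index=ids, columns=cols),
        level=pd.DataFrame(level, index=ids, columns=cols),
        retained=retained,
        posterior_min=posterior_min,
    )


def calls_to_frame(calls: StatusCallSet) -> pd.DataFrame:
    """Long-format calls table (region_id, sample, status, posterior, level)."""
    frames = []
    for name, df in (
        ("status", calls.status),
        ("posterior", calls.posterior),
        ("level", calls.level),
    ):
        long = df.stack().rename(name)
        long.index.names = ["region_id", "sample"]
        frames.append(long)
    out = pd.concat(frames, axis=1).reset_index()
    out["retained"] = calls.retained.reindex(out["region_id"]).to_numpy()
    return out
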