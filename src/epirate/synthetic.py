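"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates a selfing mutation-accumulation experiment: a random
genome with gene-like and TE-like blocks, a single-seed-descent pedigree
with sequenced sibling plants, per-region epigenotypes evolving under the
selfing Markov inheritance model, and bisulfite read counts emitted per
cytosine with status-dependent methylation probabilities and overdispersed
coverage.  Everything is deterministic under a seed, and the outputs are
byte-valid inputs for the reading side of each pipeline module.

Default emission levels (0.02 / 0.5 / 0.9 for U / I / M reads) follow the
observed per-status region methylation-level distributions in Arabidopsis
MA lines, with bisulfite non-conversion folded into the U level; coverage
is negative-binomial with mean 10, a realistic WGBS depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .divergence import Pedigree
from .rate_models import equilibrium, transition_matrix
from .segmentation import Region

#: Sequenced generations per branch for the four MA pedigree layouts.
#: Branch counts and sampled generations follow the published designs
#: (12 branches sampled at G3/G31/G32; 7 branches at G3 and G31; one branch
#: at nine generations; two branches at five generations).
PEDIGREE_PRESETS: dict[str, list[list[int]]] = {
    "MA1_1": [[3], [3], [31], [31], [31], [31], [31], [31], [32], [32], [32], [32]],
    "MA1_2": [[3, 31]] * 7,
    "MA1_3": [[3, 7, 11, 15, 18, 22, 26, 29, 31]],
    "MA2_3": [[3, 10, 17, 24, 31], [3, 10, 17, 24, 31]],
}

DEFAULT_EMISSION = {"U": 0.02, "I": 0.5, "M": 0.9}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic MA experiment.

    Defaults reproduce the genome-wide CG setting: gain rate alpha =
    1.2e-4 and loss rate beta = 4.6e-4 per haploid epiallele per
    generation, neutral inheritance, read emission 0.02/0.5/0.9 and
    negative-binomial coverage with mean 10.
    """

    seed: int = 0
    pedigree_preset: str = "MA1_1"
    custom_branches: list[list[int]] | None = None
    n_regions: int = 10_000
    alpha: float = 1.2e-4
    beta: float = 4.6e-4
    s: float = 0.0
    kind: str = "ABneutral"
    emission: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EMISSION))
    coverage_mean: float = 10.0
    coverage_dispersion: float = 5.0
    genome_length: int = 100_000
    gc_content: float = 0.36
    cg_enrichment: float = 2.0


def build_pedigree(
    preset: str | None = "MA1_1", branches: list[list[int]] | None = None
) -> Pedigree:
    """A single-seed-descent pedigree from a preset or a custom branch spec.

    ``branches`` lists, per branch, the generations at which a sibling plant
    was sequenced; each branch descends from the common founder at
    generation 0.  Propagation nodes are unsequenced; every sequenced plant
    is a leaf sibling hanging off the propagation chain.
    """
    if branches is None:
        if preset not in PEDIGREE_PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; choose from {sorted(PEDIGREE_PRESETS)}"
            )
        branches = PEDIGREE_PRESETS[preset]
    ped = Pedigree()
    ped.add_node("F", 0)
    for b, seq_gens in enumerate(branches, start=1):
        seq_gens = sorted(set(seq_gens))
        if not seq_gens or seq_gens[0] < 1:
            raise ValueError(f"branch {b}: sequenced generations must be >= 1")
        prev = "F"
        last = seq_gens[-1]
        for g in range(1, last + 1):
            if g == last:
                # terminal sequenced plant ends the chain
                ped.add_node(f"B{b}_S{g}", g, parent=prev, sequenced=True)
            else:
                node = f"B{b}_P{g}"
                ped.add_node(node, g, parent=prev)
                if g in seq_gens:
                    ped.add_node(f"B{b}_S{g}", g, parent=prev, sequenced=True)
                prev = node
    return ped


def synthetic_regions(
    n_regions: int,
    rng: np.random.Generator,
    chrom: str = "chr1",
    context: str = "CG",
) -> list[Region]:
    """Abstract CG-cluster regions on a virtual chromosome.

    Region shapes mimic the segmentation output: ~10% duplets (one CG
    dyad), the rest multiplets with 2-33 dyads spread over spans up to
    185 bp.  No genome sequence is materialised, which keeps large-scale
    simulation studies fast; member cytosine positions are still concrete
    so the count-emission and aggregation paths are exercised for real.
    """
    regions = []
    pos = 10
    for i in range(n_regions):
        if rng.random() < 0.10:
            dyads = 1
        else:
            dyads = int(rng.integers(2, 34))
        start = pos
        sites = []
        p = start
        for _ in range(dyads):
            sites.extend([p, p + 1])
            p += 2 + int(rng.integers(0, max(2, 180 // max(dyads, 1))))
        end = sites[-1] + 1
        span = end - start
        if span > 185:  # resample spacing down to the cap
            scale = 184 / span
            sites = [start + int((q - start) * scale) for q in sites]
            sites = sorted(set(sites))
            if len(sites) % 2:
                sites.append(sites[-1] + 1)
            end = sites[-1] + 1
        regions.append(Region(chrom, start, end, context, sites))
        pos = end + 200
    return regions


def evolve_methylomes(
    pedigree: Pedigree,
    n_regions: int,
    alpha: float,
    beta: float,
    s: float = 0.0,
    kind: str = "ABneutral",
    seed: int | np.random.Generator = 0,
    founder_states: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Evolve per-region epigenotypes k in {0,1,2} down the pedigree.

    Founder states are drawn from the model equilibrium unless given
    explicitly; each parent->child edge applies one draw from the
    transition matrix row, independently per region.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = transition_matrix(alpha, beta, s, kind)
    if founder_states is None:
        if kind != "ABnull" and (alpha == 0 or beta == 0):
            raise ValueError(
                "no equilibrium founder distribution when alpha or beta is 0; "
                "pass founder_states explicitly"
            )
        pi = equilibrium(T) if kind != "ABnull" else np.array([0.5, 0.0, 0.5])
        founder_states = rng.choice(3, size=n_regions, p=pi)
    cum = np.cumsum(T, axis=1)
    states = {pedigree.founder: np.asarray(founder_states, dtype=np.int8)}
    for node_id in pedigree.topological_order():
        node = pedigree.nodes[node_id]
        if node.parent is None:
            continue
        parent_states = states[node.parent]
        u = rng.random(n_regions)
        child = (u[:, None] > cum[parent_states]).sum(axis=1)
        states[node_id] = child.astype(np.int8)
    return states


def emit_counts(
    states: dict[str, np.ndarray],
    regions: list[Region],
    pedigree: Pedigree,
    emission: dict[str, float] | None = None,
    coverage_mean: float = 10.0,
    coverage_dispersion: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-cytosine count table for every sequenced sample.

    Coverage per cytosine is negative-binomial (mean ``coverage_mean``,
    shape ``coverage_dispersion``); methylated reads are binomial with the
    status-conditional methylation probability of the region's true state.
    Output columns match the pipeline's count-table dialect.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    emission = dict(DEFAULT_EMISSION if emission is None else emission)
    for v in emission.values():
        if not 0 <= v <= 1:
            raise ValueError("emission probabilities must lie in [0, 1]")
    p_by_state = np.array([emission["U"], emission["I"], emission["M"]])
    samples = pedigree.sequenced_samples
    chrom = np.concatenate([[r.chrom] * r.n_c for r in regions])
    pos = np.concatenate([np.asarray(r.sites) for r in regions]).astype(int)
    strand = np.where(np.arange(pos.size) % 2 == 0, "+", "-")
    context = np.concatenate([[r.context] * r.n_c for r in regions])
    region_of_site = np.concatenate(
        [np.full(r.n_c, i) for i, r in enumerate(regions)]
    )
    data = {"chrom": chrom, "pos": pos, "strand": strand, "context": context}
    nb_n = coverage_dispersion
    nb_p = nb_n / (nb_n + coverage_mean)
    for s in samples:
        p_site = p_by_state[states[s][region_of_site]]
        total = rng.negative_binomial(nb_n, nb_p, size=pos.size)
        meth = rng.binomial(total, p_site)
        data[f"meth_{s}"] = meth
        data[f"total_{s}"] = total
    return pd.DataFrame(data)


def simulate_genome(
    length: int = 100_000,
    seed: int | np.random.Generator = 0,
    gc_content: float = 0.36,
    cg_enrichment: float = 2.0,
    block_length: int = 3_000,
    chrom: str = "chr1",
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """A random chromosome with planted gene/TE blocks and a zone partition.

    Alternating gene-like and TE-like blocks are tiled along the sequence
    with intergenic spacers; gene blocks carry ``cg_enrichment``-fold more
    CG dinucleotides than the base composition implies.  Returns
    (sequences, annotation table with chrom/start/end/feature/name/strand,
    zone partition with chrom/start/end/zone — centromere in the middle
    flanked by pericentromeres, arms outside).
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1 kb")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base_p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def _block(n: int, enrich: float) -> np.ndarray:
        seq = bases[rng.choice(4, size=n, p=base_p)]
        # plant extra CG dinucleotides on top of the iid background;
        # enrich = 1 means background level (nothing planted)
        p_cg = min(0.5, (gc_content / 2) ** 2 * max(enrich - 1.0, 0.0))
        hits = np.nonzero(rng.random(n - 1) < p_cg)[0]
        for h in hits:
            seq[h], seq[h + 1] = ord("C"), ord("G")
        return seq

    chunks: list[np.ndarray] = []
    rows = []
    pos = 0
    gene_i = te_i = 0
    kind_cycle = ["intergenic", "gene", "intergenic", "TE"]
    k = 0
    while pos < length:
        n = min(block_length, length - pos)
        kind = kind_cycle[k % len(kind_cycle)]
        k += 1
        if kind == "gene":
            gene_i += 1
            chunks.append(_block(n, cg_enrichment))
            strand = "+" if gene_i % 2 else "-"
            rows.append((chrom, pos, pos + n, "gene", f"gene{gene_i:04d}", strand))
        elif kind == "TE":
            te_i += 1
            chunks.append(_block(n, cg_enrichment * 0.7))
            rows.append((chrom, pos, pos + n, "TE", f"te{te_i:04d}", "+"))
        else:
            chunks.append(_block(n, 1.0))
        pos += n
    seq = "".join(chr(c) for c in np.concatenate(chunks))
    annotation = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "feature", "name", "strand"]
    )
    c0, c1 = int(length * 0.45), int(length * 0.55)
    p0, p1 = int(length * 0.30), int(length * 0.70)
    partition = pd.DataFrame(
        [
            (chrom, 0, p0, "arm"),
            (chrom, p0, c0, "pericentromere"),
            (chrom, c0, c1, "centromere"),
            (chrom, c1, p1, "pericentromere"),
            (chrom, p1, length, "arm"),
        ],
        columns=["chrom", "start", "end", "zone"],
    )
    return {chrom: seq}, annotation, partition


def end_to_end_recovery(
    config: SimulationConfig,
    restarts: int = 10,
    n_bootstrap: int = 100,
    fit_kinds: tuple[str, ...] = ("ABneutral",),
) -> dict:
    """Simulate one experiment, run calling -> divergence -> fitting, and
    report parameter recovery against the known truth.

    Returns a dict with the fitted rates, relative errors, bootstrap CIs
    and whether each CI covers the true value, plus stage-wise retention.
    """
    from .divergence import divergence_table, pair_weight_matrix, state_frequencies
    from .rate_models import fit_all_models, region_bootstrap
    from .status_calling import (
        aggregate_counts,
        call_status,
        coverage_filter,
        fit_status_model,
    )

    ped, regions, states, counts = simulate_experiment(config)
    rcm = aggregate_counts(counts, regions)
    cov_mask = coverage_filter(rcm)
    passing = rcm.meth.index[cov_mask]
    model = fit_status_model(
        rcm.meth.loc[passing].to_numpy(), rcm.total.loc[passing].to_numpy()
    )
    calls = call_status(rcm, model, region_mask=cov_mask)
    records = divergence_table(ped, calls.status, calls.retained)
    freqs = state_frequencies(calls.status, calls.retained)
    fits = fit_all_models(
        records,
        restarts=restarts,
        seed=config.seed,
        n_bootstrap=0,
        kinds=fit_kinds,
        observed_meth_fraction=float(freqs[2]),
    )
    fit = fits.get("ABneutral") or next(iter(fits.values()))
    if n_bootstrap > 0 and fit.kind != "ABnull":
        ti, tj, W, m_frac = pair_weight_matrix(ped, calls.status, calls.retained)
        region_bootstrap(fit, ti, tj, W, m_frac, n_bootstrap, seed=config.seed)
    rel_err_alpha = abs(fit.alpha - config.alpha) / config.alpha if config.alpha else float("nan")
    rel_err_beta = abs(fit.beta - config.beta) / config.beta if config.beta else float("nan")
    report = {
        "true_alpha": config.alpha,
        "true_beta": config.beta,
        "fits": fits,
        "records": records,
        "alpha_hat": fit.alpha,
        "beta_hat": fit.beta,
        "rel_err_alpha": rel_err_alpha,
        "rel_err_beta": rel_err_beta,
        "n_regions_simulated": config.n_regions,
        "n_regions_retained": int(calls.retained.sum()),
        "retention_coverage": float(cov_mask.mean()),
        "retention_final": float(calls.retained.mean()),
    }
    if fit.ci95:
        report["alpha_ci"] = fit.ci95["alpha"]
        report["beta_ci"] = fit.ci95["beta"]
        report["alpha_covered"] = bool(
            fit.ci95["alpha"][0] <= config.alpha <= fit.ci95["alpha"][1]
        )
        report["beta_covered"] = bool(
            fit.ci95["beta"][0] <= config.beta <= fit.ci95["beta"][1]
        )
    return report


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[Pedigree, list[Region], dict[str, np.ndarray], pd.DataFrame]:
    """Pedigree, regions, true states and count table for one experiment."""
    rng = np.random.default_rng(config.seed)
    ped = build_pedigree(config.pedigree_preset, config.custom_branches)
    regions = synthetic_regions(config.n_regions, rng)
    states = evolve_methylomes(
        ped,
        config.n_regions,
        config.alpha,
        config.beta,
        config.s,
        config.kind,
        seed=rng,
    )
    counts = emit_counts(
        states,
        regions,
        ped,
        emission=config.emission,
        coverage_mean=config.coverage_mean,
        coverage_dispersion=config.coverage_dispersion,
        seed=rng,
    )
    return ped, regions, states, counts
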