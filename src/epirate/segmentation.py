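"""Context-specific cytosine-cluster segmentation of a plant genome.

Plant methylomes are organised around three sequence contexts — CG, CHG and
CHH (H = A, C or T) — each maintained by a different pathway.  This module
partitions a genome into non-overlapping clusters of context cytosines by a
seed-and-merge procedure: strand-symmetric dyads (CG), triads (CHG) or single
cytosines (CHH) seed the clusters, and neighbouring clusters are merged in
order of increasing gap until either the gap or the combined span exceeds a
cap (default 185 bp, the scale of one nucleosome plus linker, where the
methylation autocorrelation drops off).  Fixed-width genome bins are provided
as the conventional baseline, and the autocorrelation profile that motivates
the span cap can be recomputed from any per-cytosine methylation levels.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")

#: H in the IUPAC sense used for methylation contexts: anything but G.
_H = frozenset(b"ACT")

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANTGCAN")

#: Minimal within-seed gap per context: 0 for a CG dyad (no base between the
#: two Cs), 1 for a CHG triad (the H base), 0 for single-cytosine CHH seeds.
MIN_DISTANCE = {"CG": 0, "CHG": 1, "CHH": 0}

DEFAULT_MAX_SPAN = 185


@dataclass(frozen=True)
class CytosineSite:
    """A single cytosine with its strand and trinucleotide context."""

    chrom: str
    pos: int
    strand: str
    context: str


@dataclass
class Region:
    """A cluster of same-context cytosines on one chromosome.

    ``start``/``end`` span from the first member cytosine to one past the
    last; ``sites`` holds member C positions from both strands.
    """

    chrom: str
    start: int
    end: int
    context: str
    sites: list[int] = field(default_factory=list)

    @property
    def n_c(self) -> int:
        return len(self.sites)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def density(self) -> float:
        return self.n_c / self.span if self.span > 0 else float("nan")

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.context}"


@dataclass
class AutocorrelationProfile:
    """Pearson correlation of methylation levels vs. pair distance in bp."""

    context: str
    distances: np.ndarray
    r: np.ndarray
    n_pairs: np.ndarray

    def defined(self) -> np.ndarray:
        """Boolean mask of distances where the correlation is defined."""
        return ~np.isnan(self.r)


def _validate_context(context: str) -> None:
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}; expected one of {CONTEXTS}")


def scan_cytosines(sequences: dict[str, str], context: str) -> list[CytosineSite]:
    """Locate every cytosine of ``context`` on both strands of ``sequences``.

    A forward-strand C at position ``i`` is CG when followed by G, CHG when
    followed by H then G, and CHH when followed by two H bases; the reverse
    strand is read 5'->3' on the reverse complement.  Cytosines whose
    context cannot be resolved (Ns, or too close to the 3' end of their
    strand) are skipped.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to sequence string.
    context
        One of ``"CG"``, ``"CHG"``, ``"CHH"``.

    Returns
    -------
    list of :class:`CytosineSite`, sorted by (chrom, pos).
    """
    _validate_context(context)
    if not sequences:
        raise ValueError("empty sequence set")
    sites: list[CytosineSite] = []
    for chrom, seq in sequences.items():
        b = seq.upper().encode("ascii")
        n = len(b)
        arr = np.frombuffer(b, dtype=np.uint8)
        rc = np.frombuffer(b.translate(_COMPLEMENT)[::-1], dtype=np.uint8)
        for strand, a in (("+", arr), ("-", rc)):
            is_c = a == ord("C")
            nxt1 = np.empty(n, dtype=np.uint8)
            nxt2 = np.empty(n, dtype=np.uint8)
            nxt1[:-1], nxt1[-1] = a[1:], 0
            nxt2[:-2], nxt2[-2:] = a[2:], 0
            is_g1 = nxt1 == ord("G")
            is_h1 = (nxt1 == ord("A")) | (nxt1 == ord("C")) | (nxt1 == ord("T"))
            is_g2 = nxt2 == ord("G")
            is_h2 = (nxt2 == ord("A")) | (nxt2 == ord("C")) | (nxt2 == ord("T"))
            if context == "CG":
                hit = is_c & is_g1
            elif context == "CHG":
                hit = is_c & is_h1 & is_g2
            else:
                hit = is_c & is_h1 & is_h2
            idx = np.nonzero(hit)[0]
            if strand == "-":
                idx = n - 1 - idx
            sites.extend(CytosineSite(chrom, int(p), strand, context) for p in idx)
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def build_seeds(sites: list[CytosineSite], context: str) -> list[Region]:
    """Group scanned sites into seed regions.

    CG sites pair into strand-symmetric dyads (+C at p with -C at p+1,
    span 2): a forward CG always implies the reverse CG, so an unpaired CG
    site indicates an inconsistent scan and raises.  CHG triads (+C at p
    with -C at p+2, span 3) pair only when the motif is palindromic (CAG /
    CTG); a CCG cytosine has no CHG partner — the opposite-strand C sits in
    CG context — and seeds alone.  Each CHH cytosine is its own single-base
    seed.

    Raises
    ------
    ValueError
        If a CG site lacks its symmetric partner (inconsistent scan).
    """
    _validate_context(context)
    seeds: list[Region] = []
    if context == "CHH":
        for s in sites:
            seeds.append(Region(s.chrom, s.pos, s.pos + 1, context, [s.pos]))
        seeds.sort(key=lambda r: (r.chrom, r.start))
        return seeds

    offset = 1 if context == "CG" else 2
    by_chrom: dict[str, dict[tuple[int, str], CytosineSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, {})[(s.pos, s.strand)] = s
    for chrom in sorted(by_chrom):
        lookup = by_chrom[chrom]
        claimed: set[tuple[int, str]] = set()
        for (pos, strand) in sorted(lookup):
            if (pos, strand) in claimed:
                continue
            if strand == "+":
                partner = (pos + offset, "-")
            else:
                partner = (pos - offset, "+")
            if partner not in lookup:
                if context == "CG":
                    raise ValueError(
                        f"CG site {chrom}:{pos}({strand}) lacks its "
                        f"symmetric partner at {partner[0]}({partner[1]})"
                    )
                seeds.append(Region(chrom, pos, pos + 1, context, [pos]))
                claimed.add((pos, strand))
                continue
            claimed.add((pos, strand))
            claimed.add(partner)
            lo = min(pos, partner[0])
            seeds.append(Region(chrom, lo, lo + offset + 1, context, [lo, lo + offset]))
    seeds.sort(key=lambda r: (r.chrom, r.start))
    return seeds


def merge_regions(
    seeds: list[Region],
    max_span: int = DEFAULT_MAX_SPAN,
    context: str | None = None,
) -> list[Region]:
    """Merge seed regions by iteratively increasing gap distance.

    At each gap distance d (starting one above the context's minimal
    within-seed distance, up to ``max_span``) the cluster list is scanned
    left-to-right and every adjacent pair with inter-cluster gap <= d whose
    merged span would not exceed ``max_span`` is merged; scans repeat at a
    given d until no merge applies.  A pair blocked by the span cap is
    skipped, not frozen — each member may still merge on its other side.

    The input may span several chromosomes; merging never crosses a
    chromosome boundary.
    """
    if not seeds:
        return []
    ctx = context or seeds[0].context
    _validate_context(ctx)
    out: list[Region] = []
    by_chrom: dict[str, list[Region]] = {}
    for r in seeds:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        out.extend(_merge_one_chrom(by_chrom[chrom], max_span, MIN_DISTANCE[ctx]))
    return out


def _merge_one_chrom(seeds: list[Region], max_span: int, min_dist: int) -> list[Region]:
    prev_end = -1
    for r in seeds:
        if r.start < prev_end:
            raise ValueError("seeds must be sorted and non-overlapping")
        prev_end = r.end
    clusters = [Region(r.chrom, r.start, r.end, r.context, list(r.sites)) for r in seeds]
    for d in range(min_dist + 1, max_span + 1):
        while True:
            merged_any = False
            new: list[Region] = []
            i = 0
            while i < len(clusters):
                cur = clusters[i]
                # chain rightward: a freshly merged cluster may absorb the
                # next one too, as long as the span cap allows
                while (
                    i + 1 < len(clusters)
                    and clusters[i + 1].start - cur.end <= d
                    and clusters[i + 1].end - cur.start <= max_span
                ):
                    nxt = clusters[i + 1]
                    cur = Region(
                        cur.chrom, cur.start, nxt.end, cur.context, cur.sites + nxt.sites
                    )
                    merged_any = True
                    i += 1
                new.append(cur)
                i += 1
            clusters = new
            if not merged_any:
                break
    return clusters


def segment(
    sequences: dict[str, str],
    context: str,
    max_span: int = DEFAULT_MAX_SPAN,
) -> list[Region]:
    """Scan, seed and merge in one call: full segmentation for one context."""
    sites = scan_cytosines(sequences, context)
    return merge_regions(build_seeds(sites, context), max_span, context)


def bin_genome(
    chrom_lengths: dict[str, int],
    width: int = 100,
    sites: list[CytosineSite] | None = None,
    context: str = "CG",
) -> list[Region]:
    """Partition chromosomes into fixed-width bins; the trailing partial bin
    is kept.  When ``sites`` is given, member cytosines of ``context`` are
    assigned to bins by position; bins without member cytosines have n_c = 0.
    """
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    by_chrom: dict[str, list[int]] = {}
    if sites is not None:
        for s in sites:
            if s.context == context:
                by_chrom.setdefault(s.chrom, []).append(s.pos)
    bins: list[Region] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        positions = np.sort(np.asarray(by_chrom.get(chrom, []), dtype=int))
        for start in range(0, length, width):
            end = min(start + width, length)
            lo = np.searchsorted(positions, start, side="left")
            hi = np.searchsorted(positions, end, side="left")
            bins.append(Region(chrom, start, end, context, [int(p) for p in positions[lo:hi]]))
    return bins


def autocorrelation(
    positions: np.ndarray,
    levels: np.ndarray,
    d_max: int,
    chroms: np.ndarray | None = None,
    context: str = "CG",
) -> AutocorrelationProfile:
    """Pearson autocorrelation of methylation levels by pair distance.

    For each distance d in 1..``d_max``, correlates the levels of all
    same-chromosome cytosine pairs exactly d bp apart (strands pooled).
    Entries with fewer than two pairs, or zero variance on either side,
    are flagged undefined (NaN).
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    positions = np.asarray(positions)
    levels = np.asarray(levels, dtype=float)
    if chroms is None:
        chroms = np.zeros(len(positions), dtype=int)
    chroms = np.asarray(chroms)
    order = np.lexsort((positions, chroms))
    positions, levels, chroms = positions[order], levels[order], chroms[order]

    distances = np.arange(1, d_max + 1)
    r = np.full(d_max, np.nan)
    n_pairs = np.zeros(d_max, dtype=int)
    sums = np.zeros((d_max, 5))  # sx, sy, sxx, syy, sxy — pooled over chromosomes
    for ci in np.unique(chroms):
        m = chroms == ci
        pos_c, lev_c = positions[m], levels[m]
        for k, d in enumerate(distances):
            idx = np.searchsorted(pos_c, pos_c + d)
            ok = (idx < len(pos_c)) & (pos_c[np.minimum(idx, len(pos_c) - 1)] == pos_c + d)
            n_pairs[k] += int(ok.sum())
            if not ok.any():
                continue
            x = lev_c[ok]
            y = lev_c[idx[ok]]
            sums[k] += (x.sum(), y.sum(), (x * x).sum(), (y * y).sum(), (x * y).sum())
    for k in range(d_max):
        n = n_pairs[k]
        if n < 2:
            continue
        sx, sy, sxx, syy, sxy = sums[k]
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        if vx <= 1e-12 or vy <= 1e-12:
            continue
        r[k] = (sxy - sx * sy / n) / np.sqrt(vx * vy)
    return AutocorrelationProfile(context, distances, r, n_pairs)


def region_summary(regions: list[Region]) -> dict:
    """Summary statistics over a region list: median/max cytosine count,
    median density, and the fraction of regions with at most two cytosines.
    """
    if not regions:
        raise ValueError("empty region list")
    n_c = np.array([r.n_c for r in regions])
    density = np.array([r.density for r in regions])
    spans = np.array([r.span for r in regions])
    return {
        "n_regions": len(regions),
        "median_n_c": float(np.median(n_c)),
        "max_n_c": int(n_c.max()),
        "median_density": float(np.median(density)),
        "median_span": float(np.median(spans)),
        "frac_le2_c": float((n_c <= 2).mean()),
    }


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    """Tabulate regions as a DataFrame (BED-like, 0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "region_id": [r.region_id for r in regions],
            "n_c": [r.n_c for r in regions],
            "context": [r.context for r in regions],
            "density": [r.density for r in regions],
        }
    )
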