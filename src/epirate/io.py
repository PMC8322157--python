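"""Readers and writers for the pipeline's file dialects.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based conventions of the count TSV and GFF3 happens only at the file
boundary.  BED files are 0-based half-open natively.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .divergence import Pedigree
from .segmentation import Region


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA (optionally gzipped) to {name: sequence}."""
    with _open_text(path) as fh:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_counts_tsv(path) -> pd.DataFrame:
    """Per-cytosine count table; file positions are 1-based, returned 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "strand", "context"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} lacks columns {sorted(missing)}")
    df["pos"] = df["pos"].astype(int) - 1
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def read_pedigree_yaml(path) -> Pedigree:
    """Pedigree YAML: a ``nodes`` list of {id, generation, parent, sequenced}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    ped = Pedigree()
    nodes = doc["nodes"] if isinstance(doc, dict) else doc
    for n in sorted(nodes, key=lambda n: n["generation"]):
        ped.add_node(
            str(n["id"]),
            int(n["generation"]),
            parent=None if n.get("parent") in (None, "") else str(n["parent"]),
            sequenced=bool(n.get("sequenced", False)),
        )
    ped.founder  # validates single root
    return ped


def write_pedigree_yaml(pedigree: Pedigree, path) -> None:
    nodes = [
        {
            "id": n.node_id,
            "generation": n.generation,
            "parent": n.parent,
            "sequenced": n.sequenced,
        }
        for n in (pedigree.nodes[i] for i in pedigree.topological_order())
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"nodes": nodes}, fh, sort_keys=False)


def read_gff3(path, feature_types: set[str] | None = None) -> pd.DataFrame:
    """GFF3 to a table with chrom, start (0-based), end, feature, name, strand.

    The Name/ID attribute becomes ``name``; rows can be restricted to
    ``feature_types``.  Feature types five_prime_UTR / three_prime_UTR are
    normalised to UTR5 / UTR3, transposable_element* to TE.
    """
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            ftype = f[2]
            if ftype in ("five_prime_UTR", "5UTR"):
                ftype = "UTR5"
            elif ftype in ("three_prime_UTR", "3UTR"):
                ftype = "UTR3"
            elif ftype.startswith("transposable_element") or ftype == "transposon":
                ftype = "TE"
            if feature_types is not None and ftype not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or ""
            rows.append((f[0], int(f[3]) - 1, int(f[4]), ftype, name, f[6]))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "feature", "name", "strand"]
    )


def write_gff3(annotation: pd.DataFrame, path, source: str = "epirate") -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            strand = getattr(row, "strand", "+")
            name = getattr(row, "name", "") or f"{row.feature}_{row.start}"
            fh.write(
                f"{row.chrom}\t{source}\t{row.feature}\t{row.start + 1}\t{row.end}"
                f"\t.\t{strand}\t.\tID={name};Name={name}\n"
            )


def read_bed(path, names: list[str] | None = None) -> pd.DataFrame:
    """BED to a table; column 4 is kept as ``name`` (zone files use it)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    if names:
        df = df.rename(columns=dict(zip(["name"], names)))
    return df


def write_regions_bed(regions: list[Region], path) -> None:
    """Regions as BED6: name = region id, score = member cytosine count."""
    with _open_text(path, "wt") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.n_c}\t+\n")


def read_regions_bed(path, context: str | None = None) -> list[Region]:
    """Regions from the BED6 written by :func:`write_regions_bed`.

    Member cytosine positions are not stored in BED; they are recovered
    from the region id span when needed downstream via the count table, so
    the returned regions carry empty site lists unless ``context`` is CG,
    in which case only the span and count survive the round trip.
    """
    regions = []
    df = read_bed(path)
    for row in df.itertuples(index=False):
        ctx = context or str(row.name).rsplit(":", 1)[-1]
        regions.append(
            Region(str(row.chrom), int(row.start), int(row.end), ctx, [])
        )
    return regions


def write_zone_bed(partition: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        for row in partition.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.zone}\n")


def read_zone_bed(path) -> pd.DataFrame:
    df = read_bed(path)
    return df.rename(columns={"name": "zone"})[["chrom", "start", "end", "zone"]]


def read_gbm_list(path) -> set[str]:
    """Plain-text gene id list, one id per line."""
    with _open_text(path) as fh:
        return {line.strip() for line in fh if line.strip()}
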