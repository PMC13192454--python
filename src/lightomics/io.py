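"""Readers and writers for the standard formats the pipeline consumes.

Internal convention: all coordinates are 0-based half-open, on every
container.  GFF3 (1-based closed) is converted at the boundary; BED and
bedGraph are emitted natively half-open.  TSV files are tab-separated,
UTF-8, ``#``-comment, unquoted, with deterministic row order.

The annotation container derives the features the original annotation does
not carry explicitly: introns (gaps between a gene's sorted exons) and
promoters (strand-aware 2-kb windows upstream of the TSS, clipped at
contig ends).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

__all__ = [
    "AnnotationSet",
    "read_gff3",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_counts",
    "write_counts",
    "write_bed6",
    "write_bedgraph",
    "write_provenance",
    "PROMOTER_LENGTH",
]

#: promoter definition: 2 kb upstream of the transcription start, strand-aware
PROMOTER_LENGTH = 2000

FEATURE_COLUMNS = ["feature_id", "chrom", "start", "end", "strand", "ftype", "parent"]


@dataclass
class AnnotationSet:
    """Genomic features in internal (0-based half-open) coordinates.

    ``features`` holds one row per feature with columns
    ``feature_id, chrom, start, end, strand, ftype, parent`` where ftype is
    one of gene / exon / intron / promoter / TE and parent names the owning
    gene (or None).  Derived features (introns, promoters) are added by
    :meth:`build`.
    """

    features: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        features: pd.DataFrame,
        chrom_sizes: dict[str, int],
        promoter_length: int = PROMOTER_LENGTH,
    ) -> "AnnotationSet":
        """Validate gene/exon/TE rows and derive introns and promoters."""
        feats = features.copy().reset_index(drop=True)
        bad_strand = ~feats["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValueError(
                f"unknown strand for features {feats.loc[bad_strand, 'feature_id'].tolist()}"
            )
        genes = feats[feats["ftype"] == "gene"].set_index("feature_id")
        derived = []
        for gid, gene in genes.iterrows():
            exons = feats[(feats["ftype"] == "exon") & (feats["parent"] == gid)]
            exons = exons.sort_values("start")
            for _, ex in exons.iterrows():
                if ex["start"] < gene["start"] or ex["end"] > gene["end"]:
                    raise ValueError(f"exon {ex['feature_id']} outside the span of gene {gid}")
            # introns: gaps between consecutive exons
            prev_end = None
            for i, (_, ex) in enumerate(exons.iterrows()):
                if prev_end is not None and ex["start"] > prev_end:
                    derived.append(
                        dict(
                            feature_id=f"{gid}.intron{i}",
                            chrom=gene["chrom"],
                            start=int(prev_end),
                            end=int(ex["start"]),
                            strand=gene["strand"],
                            ftype="intron",
                            parent=gid,
                        )
                    )
                prev_end = max(prev_end or 0, int(ex["end"]))
            size = chrom_sizes.get(gene["chrom"])
            if gene["strand"] == "+":
                p_start = max(0, int(gene["start"]) - promoter_length)
                p_end = int(gene["start"])
            else:
                p_start = int(gene["end"])
                p_end = int(gene["end"]) + promoter_length
                if size is not None:
                    p_end = min(p_end, size)
            if p_end > p_start:
                derived.append(
                    dict(
                        feature_id=f"{gid}.promoter",
                        chrom=gene["chrom"],
                        start=p_start,
                        end=p_end,
                        strand=gene["strand"],
                        ftype="promoter",
                        parent=gid,
                    )
                )
        if derived:
            feats = pd.concat([feats, pd.DataFrame(derived)], ignore_index=True)
        feats = feats.sort_values(
            ["chrom", "start", "end", "ftype", "feature_id"], ignore_index=True
        )
        return cls(features=feats[FEATURE_COLUMNS], chrom_sizes=dict(chrom_sizes))

    def of_type(self, *ftypes: str) -> pd.DataFrame:
        return self.features[self.features["ftype"].isin(ftypes)]

    def genes(self) -> pd.DataFrame:
        return self.of_type("gene").set_index("feature_id")

    def interval_tree(self, *ftypes: str) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees over the requested feature types."""
        trees: dict[str, IntervalTree] = {}
        rows = self.of_type(*ftypes) if ftypes else self.features
        for row in rows.itertuples(index=False):
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row)
        return trees


_GFF_TYPE_IN = {"gene": "gene", "exon": "exon", "transposable_element": "TE"}
_GFF_TYPE_OUT = {"gene": "gene", "exon": "exon", "TE": "transposable_element"}


def read_gff3(path, promoter_length: int = PROMOTER_LENGTH) -> AnnotationSet:
    """Parse a GFF3 file into an :class:`AnnotationSet`.

    Gene, exon (with Parent) and transposable_element features are read;
    introns and promoters are derived.  Coordinates convert from 1-based
    closed to 0-based half-open.  Contig sizes come from
    ``##sequence-region`` pragmas when present.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    chrom_sizes: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            chrom_sizes[parts[1]] = int(parts[3])
    rows = []
    for feat in db.all_features():
        ftype = _GFF_TYPE_IN.get(feat.featuretype)
        if ftype is None:
            continue
        if feat.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {feat.strand!r} for feature {feat.id}")
        parent = feat.attributes.get("Parent", [None])[0]
        rows.append(
            dict(
                feature_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,  # 1-based closed -> 0-based half-open
                end=feat.end,
                strand=feat.strand,
                ftype=ftype,
                parent=parent,
            )
        )
    return AnnotationSet.build(pd.DataFrame(rows, columns=FEATURE_COLUMNS), chrom_sizes, promoter_length)


def write_gff3(annotation: AnnotationSet, path) -> None:
    """Write gene/exon/TE features as GFF3 (derived features are not
    serialized; readers re-derive them)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_sizes[chrom]}\n")
        rows = annotation.of_type("gene", "exon", "TE")
        for row in rows.itertuples(index=False):
            attrs = f"ID={row.feature_id}"
            if row.parent:
                attrs += f";Parent={row.parent}"
            fh.write(
                "\t".join(
                    [
                        row.chrom,
                        "lightomics",
                        _GFF_TYPE_OUT[row.ftype],
                        str(row.start + 1),  # back to 1-based closed
                        str(row.end),
                        ".",
                        row.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sorted(genome.items())]
    SeqIO.write(records, str(path), "fasta")


CYTOSINE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]
_CONTEXTS = {"CG", "CHG", "CHH"}


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a 7-column per-cytosine methylation report.

    Columns: chrom, 1-based position, strand, methylated count,
    unmethylated count, context, trinucleotide — the dialect written by
    standard bisulfite callers.  Positions are converted to 0-based.
    Zero-coverage rows are retained; malformed rows raise with their line
    number.  An empty file yields an empty frame.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            chrom, pos, strand, m, u, context, tri = parts
            try:
                pos_i, m_i, u_i = int(pos), int(m), int(u)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if m_i < 0 or u_i < 0:
                raise ValueError(f"{path}:{lineno}: negative counts")
            if context not in _CONTEXTS:
                raise ValueError(f"{path}:{lineno}: unknown context token {context!r}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            rows.append((chrom, pos_i - 1, strand, m_i, u_i, context, tri))
    return pd.DataFrame(rows, columns=CYTOSINE_COLUMNS)


def write_cytosine_report(records: pd.DataFrame, path) -> None:
    """Write records (internal 0-based positions) as a 1-based report,
    ordered genomically then by strand."""
    out = records[CYTOSINE_COLUMNS].sort_values(["chrom", "pos", "strand"], ignore_index=True)
    out = out.assign(pos=out["pos"] + 1)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "condition": str, "timepoint": str})
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "condition", "timepoint", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet misses columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("sample ids must be unique")
    bad = ~sheet["condition"].isin(["Ctrl", "R", "FR"])
    if bad.any():
        raise ValueError(f"unknown conditions: {sorted(set(sheet.loc[bad, 'condition']))}")
    sheet = sheet.copy()
    sheet["timepoint"] = sheet["timepoint"].astype(str)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_counts(path) -> tuple[pd.DataFrame, pd.Series]:
    """Counts TSV: gene_id index, ``length`` column, then one column per
    sample.  Returns (counts, lengths)."""
    table = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if "length" not in table.columns:
        raise ValueError("counts table needs a 'length' column (gene length in bp)")
    lengths = table["length"]
    counts = table.drop(columns="length")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    return counts, lengths


def write_counts(counts: pd.DataFrame, lengths: pd.Series, path) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths.reindex(counts.index))
    out.sort_index().to_csv(path, sep="\t", index_label="gene_id")


def write_bed6(intervals: pd.DataFrame, path) -> None:
    """BED6 from a frame with chrom/start/end/name and optional score,
    strand columns (half-open coordinates pass through natively)."""
    df = intervals.copy()
    if "score" not in df.columns:
        df["score"] = 0
    if "strand" not in df.columns:
        df["strand"] = "."
    df = df[["chrom", "start", "end", "name", "score", "strand"]]
    df.sort_values(["chrom", "start", "end", "name"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_bedgraph(records: pd.DataFrame, path, value_column: str = "level") -> None:
    """Single-base bedGraph track (e.g. per-cytosine methylation level)."""
    df = records.sort_values(["chrom", "pos"])
    with open(path, "w", encoding="utf-8") as fh:
        for row in df.itertuples(index=False):
            val = getattr(row, value_column)
            if pd.isna(val):
                continue
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{val:.6g}\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path, *, stage: str, params: dict, inputs: dict[str, str] | None = None, seed=None) -> None:
    """Per-stage provenance block: parameters, seed and input hashes.

    Deliberately timestamp-free so identical runs are byte-identical.
    """
    block = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "input_sha256": inputs or {},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(block, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
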