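"""Readers, writers and shared domain types.

All genomic coordinates are 0-based half-open internally. BED files are
native; the probe manifest stores 1-based positions on disk (the convention
of Illumina's MAPINFO column) and is converted on read/write. A probe at
position ``p`` overlaps an interval ``(s, e)`` iff ``s <= p < e``.

Text formats are plain TSV with deterministic column order; floats are
written with 6 decimals so that write→read→write round-trips are
byte-identical.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violate a domain invariant."""


REGION_CATEGORIES = (
    "TSS1500",
    "TSS200",
    "UTR5",
    "FirstExon",
    "Body",
    "UTR3",
    "Intergenic",
)
GENE_LINKED_CATEGORIES = ("TSS1500", "TSS200", "UTR5", "FirstExon", "Body", "UTR3")
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
ISLAND_FEATURES = ("Island", "Shore", "Shelf")

CORE_GROUPS = ("ALK_POS", "ALK_NEG", "CONTROL")
REFERENCE_PREFIX = "REFERENCE_STAGE:"

_FLOAT_FMT = "%.6f"

MANIFEST_COLUMNS = (
    "probe_id",
    "chrom",
    "pos",
    "strand",
    "gene",
    "region_category",
    "island_relation",
)


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def valid_group(group: str) -> bool:
    return group in CORE_GROUPS or (
        group.startswith(REFERENCE_PREFIX) and len(group) > len(REFERENCE_PREFIX)
    )


# ---------------------------------------------------------------------------
# Probe manifest


@dataclass
class ProbeAnnotationTable:
    """Per-probe genomic/gene/region/island metadata.

    ``records`` holds one row per (probe, gene, region_category) membership —
    a probe annotated ``"G1;G2"`` / ``"TSS200;Body"`` on disk contributes two
    rows. ``probes`` is the unique per-probe view (probe_id, chrom, pos,
    strand, island_relation) used as the universe for enrichment backgrounds.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"manifest missing required column(s): {missing}")
        self.records = self.records.reset_index(drop=True)
        bad_cat = set(self.records["region_category"]) - set(REGION_CATEGORIES)
        if bad_cat:
            raise ValidationError(f"unknown region_category value(s): {sorted(bad_cat)}")
        bad_rel = set(self.records["island_relation"]) - set(ISLAND_RELATIONS)
        if bad_rel:
            raise ValidationError(f"unknown island_relation value(s): {sorted(bad_rel)}")
        if (self.records["pos"] < 0).any():
            raise ValidationError("probe positions must be >= 0")
        inter = self.records["region_category"] == "Intergenic"
        if (self.records.loc[inter, "gene"] != "").any():
            raise ValidationError("Intergenic records must carry an empty gene")
        per_probe = self.records.drop_duplicates("probe_id")
        attrs = self.records.groupby("probe_id")[["chrom", "pos", "strand", "island_relation"]]
        if (attrs.nunique() > 1).any().any():
            raise ValidationError("probe-level attributes differ across memberships")
        self.probes = per_probe.set_index("probe_id")[
            ["chrom", "pos", "strand", "island_relation"]
        ]

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index

    def __len__(self) -> int:
        return len(self.probes)


def _expand_manifest_row(row: pd.Series, lineno: int) -> list[dict]:
    genes = str(row["gene"]).split(";") if row["gene"] != "" else [""]
    cats = str(row["region_category"]).split(";")
    if len(genes) == 1 and len(cats) > 1:
        genes = genes * len(cats)
    if len(genes) != len(cats):
        raise FormatError(
            f"manifest line {lineno}: gene list and region_category list "
            f"have different lengths ({len(genes)} vs {len(cats)})"
        )
    out = []
    for g, c in zip(genes, cats):
        out.append(
            dict(
                probe_id=row["probe_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]) - 1,  # 1-based on disk -> 0-based
                strand=row["strand"],
                gene=g,
                region_category=c,
                island_relation=row["island_relation"],
            )
        )
    return out


def read_manifest(path) -> ProbeAnnotationTable:
    """Read a probe manifest TSV (see module docstring for the dialect)."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"manifest missing required column(s): {missing}")
    dup = raw["probe_id"][raw["probe_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate probe_id in manifest: {sorted(set(dup))[:5]}")
    try:
        raw["pos"] = raw["pos"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer pos in manifest: {exc}") from exc
    if (raw["pos"] < 1).any():
        raise ValidationError("manifest pos is 1-based and must be >= 1")
    rows: list[dict] = []
    for i, row in raw.iterrows():
        rows.extend(_expand_manifest_row(row, i + 2))
    return ProbeAnnotationTable(pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)))


def write_manifest(table: ProbeAnnotationTable, path) -> None:
    """Write the manifest, re-joining multi-membership probes with ';'."""
    recs = table.records
    grouped = recs.groupby("probe_id", sort=False)
    rows = []
    for pid, g in grouped:
        genes = list(g["gene"])
        cats = list(g["region_category"])
        gene = ";".join(genes) if any(x != "" for x in genes) else ""
        first = g.iloc[0]
        rows.append(
            dict(
                probe_id=pid,
                chrom=first["chrom"],
                pos=int(first["pos"]) + 1,
                strand=first["strand"],
                gene=gene,
                region_category=";".join(cats),
                island_relation=first["island_relation"],
            )
        )
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Beta matrix


@dataclass
class BetaMatrix:
    """Probes × samples methylation fractions, all finite and in [0, 1]."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.df.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("beta matrix contains non-finite values")
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValidationError("beta values must lie within [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.columns

    def values_for(self, samples) -> np.ndarray:
        return self.df[list(samples)].to_numpy(dtype=float)


def read_beta_matrix(path, manifest: ProbeAnnotationTable | None = None,
                     on_missing: str = "error") -> BetaMatrix:
    """Read a β matrix TSV (first column probe_id, header = sample ids).

    ``on_missing`` controls NA handling: ``"error"`` (default) rejects the
    file, ``"drop"`` removes probes with any missing value.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValidationError("duplicate probe_id in beta matrix")
    if df.isna().any().any():
        if on_missing == "drop":
            df = df.dropna(axis=0)
        else:
            raise ValidationError(
                "beta matrix contains missing values (pass on_missing='drop' to mask)"
            )
    if manifest is not None:
        unknown = df.index.difference(manifest.probe_ids)
        if len(unknown):
            raise ValidationError(
                f"beta matrix probes absent from manifest: {sorted(unknown)[:5]}"
            )
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.df.to_csv(path, sep="\t", index_label="probe_id", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Sample sheet


@dataclass
class SampleSheet:
    """sample_id → group mapping (ALK_POS / ALK_NEG / CONTROL / REFERENCE_STAGE:<name>)."""

    df: pd.DataFrame  # columns: sample_id, group

    def __post_init__(self) -> None:
        if list(self.df.columns[:2]) != ["sample_id", "group"]:
            raise FormatError("sample sheet requires columns: sample_id, group")
        if self.df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        bad = [g for g in self.df["group"] if not valid_group(g)]
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(set(bad))}")
        self._group = dict(zip(self.df["sample_id"], self.df["group"]))

    def group_of(self, sample_id: str) -> str:
        return self._group[sample_id]

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self._group.items() if g == group]

    def validate_against(self, beta: BetaMatrix) -> None:
        missing = [s for s in beta.sample_ids if s not in self._group]
        if missing:
            raise ValidationError(f"beta samples missing from sample sheet: {missing}")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression table


@dataclass
class ExpressionTable:
    """Genes × samples linear-scale expression, strictly positive."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            raise ValidationError("duplicate gene rows in expression table")
        vals = self.df.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals.size and vals.min() <= 0):
            raise ValidationError("expression values must be finite and > 0")


def read_expression(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionTable(df)


def write_expression(expr: ExpressionTable, path) -> None:
    expr.df.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Interval tracks (BED3)


@dataclass
class IntervalTrack:
    """Named set of 0-based half-open genomic intervals."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        iv = self.intervals.reset_index(drop=True)
        if len(iv) and (iv["start"] >= iv["end"]).any():
            raise FormatError("interval with start >= end")
        if len(iv) and (iv["start"] < 0).any():
            raise FormatError("negative interval start")
        self.intervals = iv
        self._index = {}

    def __len__(self) -> int:
        return len(self.intervals)

    def merged(self) -> "IntervalTrack":
        """Union of intervals: sorted, overlapping/adjacent pieces merged."""
        rows = []
        for chrom, g in self.intervals.groupby("chrom"):
            g = g.sort_values(["start", "end"])
            cur_s = cur_e = None
            for s, e in zip(g["start"], g["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
            ["chrom", "start"]
        )
        return IntervalTrack(self.name, df)

    def _merged_index(self) -> dict:
        if not self._index:
            m = self.merged()
            for chrom, g in m.intervals.groupby("chrom"):
                self._index[chrom] = (
                    g["start"].to_numpy(int),
                    g["end"].to_numpy(int),
                )
        return self._index

    def contains(self, chroms, positions) -> np.ndarray:
        """Vectorized point-in-track test under the half-open rule."""
        idx = self._merged_index()
        chroms = np.asarray(chroms)
        positions = np.asarray(positions, dtype=int)
        out = np.zeros(len(positions), dtype=bool)
        for chrom in np.unique(chroms):
            if chrom not in idx:
                continue
            starts, ends = idx[chrom]
            sel = chroms == chrom
            pos = positions[sel]
            i = np.searchsorted(starts, pos, side="right") - 1
            ok = (i >= 0) & (pos < ends[np.clip(i, 0, len(ends) - 1)])
            out[sel] = ok
        return out


def read_track(path, name: str | None = None) -> IntervalTrack:
    """Read a BED3+ file; extra columns are ignored, coordinates kept raw."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line {lineno}: fewer than 3 columns")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            if s >= e:
                raise FormatError(f"BED line {lineno}: start >= end")
            rows.append((chrom, s, e))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if name is None:
        name = str(path)
    return IntervalTrack(name, df)


def write_track(track: IntervalTrack, path) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Ct tables (ms-qPCR)

NO_AMP = "NA"  # on-disk token for "no amplification"


@dataclass
class CtTable:
    """Replicate-level qPCR Ct values; NaN encodes 'no amplification'.

    One row per (sample_id, assay, replicate). The fully methylated
    M.SssI-treated reference must be present as a sample for every assay
    before PMR can be computed.
    """

    df: pd.DataFrame  # columns: sample_id, assay, ct

    def __post_init__(self) -> None:
        need = ["sample_id", "assay", "ct"]
        if list(self.df.columns[:3]) != need:
            raise FormatError(f"ct table requires columns: {need}")

    def replicates(self, sample_id: str, assay: str) -> np.ndarray:
        sel = (self.df["sample_id"] == sample_id) & (self.df["assay"] == assay)
        return self.df.loc[sel, "ct"].to_numpy(dtype=float)


def read_ct_table(path) -> CtTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "assay": str},
                     na_values=[NO_AMP], keep_default_na=False)
    df["ct"] = df["ct"].astype(float)
    return CtTable(df)


def write_ct_table(table: CtTable, path) -> None:
    df = table.df.copy()
    df["ct"] = df["ct"].map(lambda x: NO_AMP if pd.isna(x) else _fmt(x))
    df.to_csv(path, sep="\t", index=False)
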