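"""Readers, writers and validated containers for the pipeline's file formats.

All tabular formats are tab-separated UTF-8 with a header row; sequences are
plain FASTA. ASV identifiers are opaque strings — tables are always joined by
id, never by position. Taxonomy is optional per ASV because classifiers leave
gaps at lower ranks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class FormatError(ValueError):
    """Raised when a file does not parse as the expected format."""


class ValidationError(ValueError):
    """Raised when parsed content violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class AsvCountTable:
    """Integer read counts, samples x ASVs; the pipeline's central input."""

    counts: pd.DataFrame  # index = sample ids, columns = ASV ids

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "sample ids")
        _check_unique(df.columns, "ASV ids")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("non-integer count in table")
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
            arr = df.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[i]!r}, ASV {df.columns[j]!r}"
            )
        if (arr.sum(axis=1) == 0).any():
            empty = df.index[arr.sum(axis=1) == 0].tolist()
            raise ValidationError(f"samples with zero total reads: {empty[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def relative(self, percent: bool = True) -> pd.DataFrame:
        """Per-sample normalized abundances (percentages by default)."""
        scale = 100.0 if percent else 1.0
        return self.counts.div(self.counts.sum(axis=1), axis=0) * scale


@dataclass
class SampleMetadata:
    """Per-sample design: species, tissue and replicate labels."""

    table: pd.DataFrame  # index = sample id; columns species, tissue, replicate

    REQUIRED = ("species", "tissue", "replicate")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def tissue_of(self) -> pd.Series:
        return self.table["tissue"]

    def species_of(self) -> pd.Series:
        return self.table["species"]

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())


@dataclass
class TaxonomyTable:
    """Rank assignments per ASV; empty strings mark unassigned ranks."""

    table: pd.DataFrame  # index = asv id; columns = TAXONOMY_RANKS

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "ASV ids")
        missing = [r for r in TAXONOMY_RANKS if r not in self.table.columns]
        if missing:
            raise ValidationError(f"taxonomy missing rank columns: {missing}")
        tbl = self.table[list(TAXONOMY_RANKS)].fillna("").astype(str)
        object.__setattr__(self, "table", tbl)

    def genus_of(self, asv_id: str) -> str:
        if asv_id not in self.table.index:
            return ""
        return str(self.table.at[asv_id, "genus"])


@dataclass
class SequenceSet:
    """Uppercase IUPAC DNA sequences keyed by record id."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for rid, seq in self.records.items():
            if not seq:
                raise ValidationError(f"empty sequence for record {rid!r}")
            bad = set(seq) - IUPAC_DNA
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValidationError(
                    f"illegal character {seq[pos]!r} in record {rid!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> str:
        return self.records[rid]

    @property
    def ids(self) -> list[str]:
        return list(self.records)


@dataclass
class ReferenceStrainSet:
    """Reference producer strains: sequence plus genus and provenance tag."""

    sequences: SequenceSet
    info: pd.DataFrame  # index = strain id; columns genus, source_tag

    def __post_init__(self) -> None:
        missing = set(self.sequences.ids) - set(self.info.index)
        if missing:
            raise ValidationError(f"strains without metadata: {sorted(missing)[:5]}")
        if (self.info["genus"].astype(str) == "").any():
            raise ValidationError("reference strain with empty genus")

    @property
    def ids(self) -> list[str]:
        return list(self.sequences.ids)


@dataclass
class MetaboliteTable:
    """Mean tissue concentrations (ug/g fresh weight) per compound."""

    table: pd.DataFrame  # columns: tissue, compound, mean_concentration

    def __post_init__(self) -> None:
        need = {"tissue", "compound", "mean_concentration"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValidationError(f"metabolite table missing columns: {sorted(missing)}")
        if self.table.duplicated(["tissue", "compound"]).any():
            raise ValidationError("duplicate (tissue, compound) row")
        if (self.table["mean_concentration"] < 0).any():
            raise ValidationError("negative metabolite concentration")

    def gradient(self, compound: str) -> pd.Series:
        """tissue -> mean concentration for one compound."""
        sub = self.table[self.table["compound"] == compound]
        if sub.empty:
            raise KeyError(f"compound {compound!r} not in metabolite table")
        return sub.set_index("tissue")["mean_concentration"]


# ---------------------------------------------------------------------------
# readers / writers


def read_asv_table(path) -> AsvCountTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        num = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path.name}: non-numeric count cell ({exc})") from exc
    arr = num.to_numpy()
    frac = arr - np.floor(arr)
    if np.abs(frac).max(initial=0) > 0:
        i, j = np.argwhere(np.abs(frac) > 0)[0]
        raise FormatError(
            f"{path.name}: non-integer count at row {num.index[i]!r}, column {num.columns[j]!r}"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"{path.name}: negative count at row {num.index[i]!r}, column {num.columns[j]!r}"
        )
    return AsvCountTable(num.astype(np.int64))


def write_asv_table(table: AsvCountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{Path(path).name}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    if "replicate" in df.columns:
        df["replicate"] = pd.to_numeric(df["replicate"]).astype(int)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "asv_id" not in df.columns:
        raise FormatError(f"{Path(path).name}: missing 'asv_id' column")
    return TaxonomyTable(df.set_index("asv_id"))


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    tax.table.to_csv(path, sep="\t", index_label="asv_id")


def read_metabolites(path) -> MetaboliteTable:
    df = pd.read_csv(path, sep="\t")
    if "mean_concentration" in df.columns:
        df["mean_concentration"] = pd.to_numeric(df["mean_concentration"])
    return MetaboliteTable(df)


def write_metabolites(tbl: MetaboliteTable, path) -> None:
    tbl.table.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> SequenceSet:
    """Parse FASTA; ids are the first whitespace token, sequences upper-cased."""
    records: dict[str, str] = {}
    rid = None
    chunks: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid is not None:
                    records[rid] = "".join(chunks)
                rid = line[1:].split()[0] if line[1:].split() else ""
                if not rid:
                    raise FormatError(f"{Path(path).name}: empty FASTA header")
                if rid in records:
                    raise FormatError(f"{Path(path).name}: duplicate record id {rid!r}")
                chunks = []
            elif line.strip():
                if rid is None:
                    raise FormatError(f"{Path(path).name}: sequence before first header")
                chunks.append(re.sub(r"\s", "", line).upper())
    if rid is not None:
        records[rid] = "".join(chunks)
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path, width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in seqs.records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_reference_strains(fasta_path, info_path) -> ReferenceStrainSet:
    seqs = read_fasta(fasta_path)
    df = pd.read_csv(info_path, sep="\t", dtype=str, keep_default_na=False)
    if "strain_id" not in df.columns:
        raise FormatError(f"{Path(info_path).name}: missing 'strain_id' column")
    return ReferenceStrainSet(seqs, df.set_index("strain_id"))


def write_reference_strains(refs: ReferenceStrainSet, fasta_path, info_path) -> None:
    write_fasta(refs.sequences, fasta_path)
    refs.info.to_csv(info_path, sep="\t", index_label="strain_id")


# ---------------------------------------------------------------------------
# cross-referencing and merging


@dataclass
class ValidationReport:
    """Outcome of cross-referencing a dataset's component files."""

    samples_without_metadata: list[str] = field(default_factory=list)
    metadata_without_counts: list[str] = field(default_factory=list)
    asvs_without_sequence: list[str] = field(default_factory=list)
    asvs_without_taxonomy: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        # missing taxonomy is a warning only: classifiers leave gaps
        return not self.samples_without_metadata and not self.asvs_without_sequence

    def messages(self) -> list[str]:
        out = []
        if self.samples_without_metadata:
            out.append(f"samples without metadata: {self.samples_without_metadata}")
        if self.metadata_without_counts:
            out.append(f"metadata rows without counts: {self.metadata_without_counts}")
        if self.asvs_without_sequence:
            out.append(f"ASVs without sequence: {self.asvs_without_sequence}")
        if self.asvs_without_taxonomy:
            out.append(f"warning, ASVs without taxonomy: {self.asvs_without_taxonomy}")
        return out


def validate_dataset(
    counts: AsvCountTable,
    meta: SampleMetadata,
    tax: TaxonomyTable | None = None,
    seqs: SequenceSet | None = None,
) -> ValidationReport:
    report = ValidationReport()
    meta_ids = set(meta.sample_ids)
    count_ids = set(counts.sample_ids)
    report.samples_without_metadata = sorted(count_ids - meta_ids)
    report.metadata_without_counts = sorted(meta_ids - count_ids)
    if seqs is not None:
        report.asvs_without_sequence = sorted(set(counts.asv_ids) - set(seqs.ids))
    if tax is not None:
        report.asvs_without_taxonomy = sorted(set(counts.asv_ids) - set(tax.table.index))
    return report


def merge_species_tables(
    a: AsvCountTable, b: AsvCountTable
) -> tuple[AsvCountTable, dict[str, int]]:
    """Union two count tables over ASV columns, zero-filling absences.

    Returns the merged table plus the overlap summary
    ``{n_a, n_b, n_shared, n_union}`` with n_union = n_a + n_b - n_shared.
    """
    shared_samples = set(a.sample_ids) & set(b.sample_ids)
    if shared_samples:
        raise ValidationError(f"duplicate sample ids across tables: {sorted(shared_samples)[:5]}")
    asv_union = list(a.asv_ids) + [x for x in b.asv_ids if x not in set(a.asv_ids)]
    merged = pd.concat([a.counts, b.counts]).reindex(columns=asv_union).fillna(0)
    merged = merged.astype(np.int64)
    n_shared = len(set(a.asv_ids) & set(b.asv_ids))
    summary = {
        "n_a": len(a.asv_ids),
        "n_b": len(b.asv_ids),
        "n_shared": n_shared,
        "n_union": len(asv_union),
    }
    return AsvCountTable(merged), summary
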