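"""Shared genomic data model and on-disk formats.

All coordinates are 0-based, half-open ``[start, end)`` — BED-native —
throughout the package. A CpG locus is identified by the position of the
C on the + strand; the strand column is carried through I/O but ignored
by analysis. Missing ratios/coverages are written as ``NA`` on disk and
held as NaN in memory, never as 0.

Formats
-------
- intervals: BED3 / BED6 (missing name/strand default to ``.``)
- methylome: TSV ``chrom  pos  strand  <sample>_ratio  <sample>_cov ...``
  with a sidecar sample sheet ``sample_id  cohort``
- gene table: TSV ``gene_id  chrom  strand  tss  body_start  body_end``
- expression: TSV ``gene_id  <sample>_tpm ...``
- survival: TSV ``patient_id  time_days  event  <covariates...>``
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

VALID_STRANDS = {"+", "-", "."}
VALID_COHORTS = ("normal", "tumor")

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "MethylomeMatrix",
    "ExpressionMatrix",
    "SurvivalTable",
    "read_methylome",
    "write_methylome",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_intervals",
    "write_intervals",
    "read_gene_table",
    "write_gene_table",
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "write_bedgraph",
    "overlap",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``score`` is carried so BED6 round-trips and scored emissions (e.g.
    DMR density scores) are lossless; analysis code ignores it.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: int = 0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise DataError(f"negative coordinate: {self.chrom}:{self.start}")
        if self.end <= self.start:
            raise DataError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise DataError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and (
            max(self.start, other.start) < min(self.end, other.end)
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS and genomic span; strand is mandatory."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise DataError(f"gene {self.gene_id}: strand must be + or -")
        if self.body_end <= self.body_start:
            raise DataError(f"gene {self.gene_id}: body_end must exceed body_start")
        if not (self.body_start <= self.tss <= self.body_end):
            raise DataError(f"gene {self.gene_id}: TSS outside gene span")


@dataclass
class MethylomeMatrix:
    """Per-CpG methylation ratios and coverages over two labeled cohorts.

    ``loci`` has columns (chrom, pos, strand) and aligns row-for-row with
    ``ratios`` and ``coverages`` (both loci x samples, NaN = missing).
    ``sample_labels`` maps sample_id -> cohort in {normal, tumor}.
    """

    loci: pd.DataFrame
    ratios: pd.DataFrame
    coverages: pd.DataFrame
    sample_labels: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.ratios.columns) != list(self.coverages.columns):
            raise DataError("ratio and coverage columns disagree")
        if len(self.loci) != len(self.ratios):
            raise DataError("loci and ratio row counts disagree")
        bad = ~self.sample_labels.isin(VALID_COHORTS)
        if bad.any():
            raise DataError(
                f"unknown cohort label(s): {sorted(self.sample_labels[bad].unique())}"
            )
        for cohort in VALID_COHORTS:
            if (self.sample_labels == cohort).sum() < 1:
                raise DataError(f"cohort {cohort!r} has no samples")
        vals = self.ratios.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
                raise DataError("methylation ratios must lie in [0, 1]")
        key = self.loci[["chrom", "pos"]]
        if not (
            key.sort_values(["chrom", "pos"], kind="stable").index == key.index
        ).all():
            raise DataError("loci must be sorted by (chrom, pos)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ratios.columns)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def cohort_samples(self, cohort: str) -> list[str]:
        return list(self.sample_labels.index[self.sample_labels == cohort])

    def cohort_ratios(self, cohort: str) -> np.ndarray:
        """loci x samples ratio array restricted to one cohort."""
        return self.ratios[self.cohort_samples(cohort)].to_numpy(float)

    def subset_loci(self, mask: np.ndarray) -> "MethylomeMatrix":
        return MethylomeMatrix(
            loci=self.loci.loc[mask].reset_index(drop=True),
            ratios=self.ratios.loc[mask].reset_index(drop=True),
            coverages=self.coverages.loc[mask].reset_index(drop=True),
            sample_labels=self.sample_labels.copy(),
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM abundances with cohort labels."""

    tpm: pd.DataFrame  # index gene_id, columns sample_id
    sample_labels: pd.Series

    def __post_init__(self) -> None:
        if self.tpm.index.duplicated().any():
            dups = self.tpm.index[self.tpm.index.duplicated()].unique()
            raise DataError(f"duplicate gene_id(s): {list(dups[:5])}")
        if (self.tpm.to_numpy(float) < 0).any():
            raise DataError("TPM values must be non-negative")
        bad = ~self.sample_labels.isin(VALID_COHORTS)
        if bad.any():
            raise DataError(
                f"unknown cohort label(s): {sorted(self.sample_labels[bad].unique())}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    def cohort_samples(self, cohort: str) -> list[str]:
        return list(self.sample_labels.index[self.sample_labels == cohort])


@dataclass
class SurvivalTable:
    """Patient follow-up with event indicator and numeric covariates."""

    data: pd.DataFrame  # patient_id, time_days, event, covariates...

    def __post_init__(self) -> None:
        required = {"patient_id", "time_days", "event"}
        missing = required - set(self.data.columns)
        if missing:
            raise DataError(f"survival table missing column(s): {sorted(missing)}")
        if (self.data["time_days"] <= 0).any():
            raise DataError("follow-up time must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise DataError("event indicator must be 0 or 1")

    @property
    def covariate_names(self) -> list[str]:
        return [
            c for c in self.data.columns if c not in ("patient_id", "time_days", "event")
        ]


# ---------------------------------------------------------------------------
# readers / writers


def read_sample_sheet(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "cohort"} <= set(df.columns):
        raise DataError(f"{path}: sample sheet needs columns sample_id, cohort")
    bad = ~df["cohort"].isin(VALID_COHORTS)
    if bad.any():
        raise DataError(
            f"{path}: unknown cohort label(s) {sorted(df.loc[bad, 'cohort'].unique())}"
        )
    return pd.Series(df["cohort"].values, index=df["sample_id"].values, name="cohort")


def write_sample_sheet(path: str | Path, labels: pd.Series) -> None:
    pd.DataFrame({"sample_id": labels.index, "cohort": labels.values}).to_csv(
        path, sep="\t", index=False
    )


def read_methylome(path: str | Path, sample_sheet: str | Path) -> MethylomeMatrix:
    """Read a per-CpG ratio/coverage TSV plus its cohort sample sheet.

    Rows are sorted by (chrom, pos) on load; ratio bounds and labels are
    validated with the offending line number in the error message.
    """
    labels = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    for col in ("chrom", "pos", "strand"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    ratio_cols = [c for c in df.columns if c.endswith("_ratio")]
    samples = [c[: -len("_ratio")] for c in ratio_cols]
    if not samples:
        raise DataError(f"{path}: no <sample>_ratio columns found")
    unknown = [s for s in samples if s not in labels.index]
    if unknown:
        raise DataError(f"{path}: sample(s) {unknown} absent from sample sheet")

    ratios = df[ratio_cols].astype(float)
    ratios.columns = samples
    bad = (ratios < 0) | (ratios > 1)
    if bad.to_numpy().any():
        row = int(np.nonzero(bad.any(axis=1).to_numpy())[0][0])
        raise DataError(
            f"{path}: line {row + 2}: methylation ratio outside [0, 1]"
        )
    cov_cols = {s: f"{s}_cov" for s in samples}
    covs = pd.DataFrame(
        {s: df[c].astype(float) if c in df.columns else np.nan for s, c in cov_cols.items()}
    )
    if (covs.fillna(0).to_numpy() < 0).any():
        raise DataError(f"{path}: negative coverage")

    loci = df[["chrom", "pos", "strand"]].copy()
    loci["pos"] = loci["pos"].astype(int)
    order = loci.sort_values(["chrom", "pos"], kind="stable").index
    return MethylomeMatrix(
        loci=loci.loc[order].reset_index(drop=True),
        ratios=ratios.loc[order].reset_index(drop=True),
        coverages=covs.loc[order].reset_index(drop=True),
        sample_labels=labels.loc[samples],
    )


def write_methylome(path: str | Path, m: MethylomeMatrix) -> None:
    out = m.loci.copy()
    for s in m.sample_ids:
        out[f"{s}_ratio"] = m.ratios[s]
        out[f"{s}_cov"] = m.coverages[s]
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_intervals(path: str | Path, track_name: str = "") -> list[GenomicInterval]:
    """Read BED3/BED6; missing name and strand default to ``.``."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}: line {lineno}: fewer than 3 BED fields")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = int(float(fields[4])) if len(fields) > 4 and fields[4] != "." else 0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
            except DataError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_intervals(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    """Write BED; BED3 when every name/strand/score is default, else BED6."""
    ivs = list(intervals)
    bed6 = any(i.name != "." or i.strand != "." or i.score != 0 for i in ivs)
    with open(path, "w") as fh:
        for i in ivs:
            if bed6:
                fh.write(f"{i.chrom}\t{i.start}\t{i.end}\t{i.name}\t{i.score}\t{i.strand}\n")
            else:
                fh.write(f"{i.chrom}\t{i.start}\t{i.end}\n")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    required = ["gene_id", "chrom", "strand", "tss", "body_start", "body_end"]
    missing = set(required) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing column(s) {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
        raise DataError(f"{path}: duplicate gene_id(s): {list(dups[:5])}")
    return [
        GeneModel(
            gene_id=r.gene_id,
            chrom=r.chrom,
            strand=r.strand,
            tss=int(r.tss),
            body_start=int(r.body_start),
            body_end=int(r.body_end),
        )
        for r in df.itertuples()
    ]


def write_gene_table(path: str | Path, genes: Sequence[GeneModel]) -> None:
    pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.strand, g.tss, g.body_start, g.body_end)
            for g in genes
        ],
        columns=["gene_id", "chrom", "strand", "tss", "body_start", "body_end"],
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path, sample_sheet: str | Path) -> ExpressionMatrix:
    labels = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise DataError(f"{path}: missing column gene_id")
    tpm_cols = [c for c in df.columns if c.endswith("_tpm")]
    samples = [c[: -len("_tpm")] for c in tpm_cols]
    unknown = [s for s in samples if s not in labels.index]
    if unknown:
        raise DataError(f"{path}: sample(s) {unknown} absent from sample sheet")
    tpm = df[tpm_cols].astype(float)
    tpm.columns = samples
    tpm.index = pd.Index(df["gene_id"], name="gene_id")
    return ExpressionMatrix(tpm=tpm, sample_labels=labels.loc[samples])


def write_expression(path: str | Path, e: ExpressionMatrix) -> None:
    out = e.tpm.copy()
    out.columns = [f"{s}_tpm" for s in out.columns]
    out.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    return SurvivalTable(data=df)


def write_survival(path: str | Path, t: SurvivalTable) -> None:
    t.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_bedgraph(path: str | Path, m: MethylomeMatrix, sample: str) -> None:
    """Export one sample's per-CpG ratios as bedGraph (NaN rows skipped)."""
    if sample not in m.sample_ids:
        raise DataError(f"unknown sample {sample!r}")
    vals = m.ratios[sample]
    with open(path, "w") as fh:
        for (chrom, pos), v in zip(
            zip(m.loci["chrom"], m.loci["pos"]), vals, strict=True
        ):
            if not np.isnan(v):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# interval overlap engine


def overlap(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (query_index, subject_index) pairs with a strict positive overlap.

    Half-open semantics: [0,10) and [10,20) do not overlap. Strand is
    ignored. Output sorted by query index then subject index. Sweep-line
    over start positions with end-ordered heaps; O((n+m) log + k pairs).
    """
    pairs: list[tuple[int, int]] = []
    by_chrom: dict[str, tuple[list[tuple[int, int, int]], list[tuple[int, int, int]]]] = {}
    for qi, iv in enumerate(query):
        by_chrom.setdefault(iv.chrom, ([], []))[0].append((iv.start, iv.end, qi))
    for si, iv in enumerate(subject):
        by_chrom.setdefault(iv.chrom, ([], []))[1].append((iv.start, iv.end, si))

    for qs, ss in by_chrom.values():
        if not qs or not ss:
            continue
        qs.sort()
        ss.sort()
        # merge both streams by start; active heaps keyed by end
        active_q: list[tuple[int, int]] = []  # (end, qi)
        active_s: list[tuple[int, int]] = []
        i = j = 0
        while i < len(qs) or j < len(ss):
            take_q = j >= len(ss) or (i < len(qs) and qs[i][0] <= ss[j][0])
            if take_q:
                start, end, qi = qs[i]
                i += 1
                while active_s and active_s[0][0] <= start:
                    heapq.heappop(active_s)
                pairs.extend((qi, si) for _, si in active_s)
                heapq.heappush(active_q, (end, qi))
            else:
                start, end, si = ss[j]
                j += 1
                while active_q and active_q[0][0] <= start:
                    heapq.heappop(active_q)
                pairs.extend((qi, si) for _, qi in active_q)
                heapq.heappush(active_s, (end, si))
    pairs.sort()
    return pairs
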