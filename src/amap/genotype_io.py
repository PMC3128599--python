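"""I/O for SNP maps, Illumina-style A/B genotype reports and sample sheets.

Genotypes follow the Illumina A/B convention: each SNP is biallelic with
strand-normalized alleles labelled A and B, so every call is one of
homA ("AA"), het ("AB"/"BA"), homB ("BB") or a no-call.  Calls are stored
as a compact ``samples x SNPs`` int8 grid; the SNP axis always follows the
map's contiguous index (sorted by chromosome, then position).

Two report dialects are supported: the GenomeStudio-like long format
(one row per sample x SNP with ``Sample ID``, ``SNP Name``, ``Allele1 - AB``,
``Allele2 - AB`` and optionally a GenTrain/GC score column) and a simple
matrix CSV (one row per sample, one column per SNP, cells like "AA").
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# genotype call codes
HOM_A = 0
HET = 1
HOM_B = 2
NOCALL = 3

CALL_LABELS = ("AA", "AB", "BB", "--")
NOCALL_TOKENS = {"--", "-", "", "NC", "NA", "nan", "None"}
STATUSES = ("affected", "carrier", "normal", "unknown")

DEFAULT_MAP_COLUMNS = ("snp_name", "chromosome", "position")


def chromosome_key(chrom: str) -> tuple:
    """Numeric-aware sort key for chromosome names ("2" < "10" < "X")."""
    parts = re.split(r"(\d+)", str(chrom))
    return tuple((0, int(p)) if p.isdigit() else (1, p) for p in parts if p)


class SnpMap:
    """Ordered, contiguously indexed SNP positions.

    Entries are sorted by (chromosome, position), chromosomes compared with
    a numeric-aware key; the resulting row index 0..N-1 is the contiguous
    index over which "consecutive SNPs" is defined for the run scan.
    Positions are 1-based; ties within a chromosome are an input error.
    """

    def __init__(self, frame: pd.DataFrame, *, presorted: bool = False):
        required = ["snp_name", "chromosome", "position_bp"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"SnpMap frame missing columns {missing}")
        df = frame.loc[:, required].copy()
        df["snp_name"] = df["snp_name"].astype(str)
        df["chromosome"] = df["chromosome"].astype(str)
        df["position_bp"] = df["position_bp"].astype(np.int64)
        if (df["position_bp"] < 1).any():
            bad = df.loc[df["position_bp"] < 1, "snp_name"].iloc[0]
            raise ValueError(f"non-positive position for SNP {bad!r}")
        if not presorted:
            df = df.sort_values(
                by=["chromosome", "position_bp"],
                key=lambda s: s.map(chromosome_key) if s.name == "chromosome" else s,
                kind="mergesort",
            )
        df = df.reset_index(drop=True)
        dup = df["snp_name"].duplicated()
        if dup.any():
            raise ValueError(f"duplicate SNP name {df.loc[dup, 'snp_name'].iloc[0]!r}")
        same_chrom = df["chromosome"].values[1:] == df["chromosome"].values[:-1]
        nondecr = df["position_bp"].values[1:] <= df["position_bp"].values[:-1]
        tied = same_chrom & nondecr
        if tied.any():
            i = int(np.flatnonzero(tied)[0]) + 1
            raise ValueError(
                "tied position within chromosome "
                f"{df['chromosome'].iat[i]!r} at {df['position_bp'].iat[i]} "
                f"(SNPs {df['snp_name'].iat[i - 1]!r}, {df['snp_name'].iat[i]!r})"
            )
        self._df = df
        self._name_to_index = {n: i for i, n in enumerate(df["snp_name"])}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "SnpMap":
        rows = list(records)
        frame = pd.DataFrame(rows, columns=["snp_name", "chromosome", "position_bp"])
        return cls(frame)

    @classmethod
    def empty(cls) -> "SnpMap":
        return cls(pd.DataFrame(columns=["snp_name", "chromosome", "position_bp"]))

    # -- accessors ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        return isinstance(other, SnpMap) and self._df.equals(other._df)

    @property
    def names(self) -> np.ndarray:
        return self._df["snp_name"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self._df["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self._df["position_bp"].to_numpy()

    def index_of(self, snp_name: str) -> int:
        try:
            return self._name_to_index[snp_name]
        except KeyError:
            raise KeyError(f"SNP {snp_name!r} not in map") from None

    def entry(self, snp_name: str) -> tuple[str, str, int, int]:
        i = self.index_of(snp_name)
        row = self._df.iloc[i]
        return (row["snp_name"], row["chromosome"], int(row["position_bp"]), i)

    def chrom_slices(self) -> list[tuple[str, int, int]]:
        """Half-open contiguous-index slices per chromosome, in map order."""
        out = []
        chroms = self.chromosomes
        i = 0
        while i < len(chroms):
            j = i
            while j < len(chroms) and chroms[j] == chroms[i]:
                j += 1
            out.append((chroms[i], i, j))
            i = j
        return out

    def subset(self, keep: np.ndarray) -> "SnpMap":
        """Re-indexed map restricted to a boolean mask over contiguous indices."""
        return SnpMap(self._df.loc[np.asarray(keep, bool)], presorted=True)

    def to_frame(self) -> pd.DataFrame:
        df = self._df.copy()
        df["contiguous_index"] = np.arange(len(df))
        return df


def read_map(
    path,
    *,
    sep: str | None = None,
    column_names: Sequence[str] = DEFAULT_MAP_COLUMNS,
) -> SnpMap:
    """Read a SNP map file (delimited text: name, chromosome, position).

    The header is optional; row order in the file is irrelevant because
    sorting and contiguous renumbering happen here.  A non-numeric position
    raises with the offending line number; duplicate names raise naming the
    SNP.  An empty file yields an empty map.
    """
    import csv

    try:
        raw = pd.read_csv(
            path, sep=sep, engine="python", header=None, dtype=str,
            comment="#", skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return SnpMap.empty()
    except csv.Error:
        # delimiter sniffing fails on blank-only content
        text = Path(path).read_text() if isinstance(path, (str, Path)) else ""
        if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
            return SnpMap.empty()
        raise
    if raw.shape[1] < 3:
        raise ValueError(f"map file needs >=3 columns, found {raw.shape[1]}")

    lowered = [str(v).strip().lower() for v in raw.iloc[0]]
    wanted = [c.lower() for c in column_names]
    has_header = not _parses_as_int(raw.iloc[0, 2])
    if has_header and all(w in lowered for w in wanted):
        cols = [lowered.index(w) for w in wanted]
    else:
        cols = [0, 1, 2]
    body = raw.iloc[1:] if has_header else raw
    offset = 2 if has_header else 1  # 1-based line number of first data row

    positions = []
    for k, v in enumerate(body.iloc[:, cols[2]]):
        try:
            positions.append(int(str(v).strip()))
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric position {v!r} at line {k + offset}"
            ) from None
    frame = pd.DataFrame(
        {
            "snp_name": body.iloc[:, cols[0]].astype(str).str.strip().values,
            "chromosome": body.iloc[:, cols[1]].astype(str).str.strip().values,
            "position_bp": positions,
        }
    )
    return SnpMap(frame)


def _parses_as_int(value) -> bool:
    try:
        int(str(value).strip())
        return True
    except (TypeError, ValueError):
        return False


def write_map(snp_map: SnpMap, path, *, sep: str = "\t") -> None:
    df = snp_map.to_frame()[["snp_name", "chromosome", "position_bp"]]
    df.columns = ["snp_name", "chromosome", "position"]
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# genotype matrix


@dataclass
class GenotypeMatrix:
    """Sample x SNP genotype grid plus map, statuses and optional per-SNP QC.

    ``calls`` is int8 with codes HOM_A/HET/HOM_B/NOCALL; columns follow
    ``snp_map`` contiguous order.  ``qc`` (if present) is a DataFrame aligned
    to the map with columns ``snp_name``, ``call_rate``, ``gentrain``.
    """

    sample_ids: list[str]
    statuses: list[str]
    calls: np.ndarray
    snp_map: SnpMap
    qc: pd.DataFrame | None = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.snp_map)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sample_ids)} samples, {len(self.snp_map)} SNPs)"
            )
        bad = set(self.statuses) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown status values {sorted(bad)}")
        if not (0 <= self.calls.min(initial=0)) or self.calls.max(initial=0) > 3:
            raise ValueError("calls contain codes outside {homA, het, homB, nocall}")
        if self.qc is not None:
            self.qc = _align_qc(self.qc, self.snp_map)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            [self.statuses[i] for i in idx],
            self.calls[idx, :] if idx else self.calls[:0, :],
            self.snp_map,
            self.qc,
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep, bool)
        qc = self.qc.loc[keep].reset_index(drop=True) if self.qc is not None else None
        return GenotypeMatrix(
            list(self.sample_ids),
            list(self.statuses),
            self.calls[:, keep],
            self.snp_map.subset(keep),
            qc,
        )

    def attach_qc(self, qc: pd.DataFrame) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids), list(self.statuses), self.calls, self.snp_map, qc
        )

    def call_rates(self) -> np.ndarray:
        """Observed per-SNP fraction of non-missing calls in this matrix."""
        if self.n_samples == 0:
            return np.zeros(self.n_snps)
        return 1.0 - (self.calls == NOCALL).mean(axis=0)


def _align_qc(qc: pd.DataFrame, snp_map: SnpMap) -> pd.DataFrame:
    for col in ("snp_name", "call_rate", "gentrain"):
        if col not in qc.columns:
            raise ValueError(f"QC frame missing column {col!r}")
    indexed = qc.set_index("snp_name")
    missing = [n for n in snp_map.names if n not in indexed.index]
    if missing:
        raise ValueError(f"QC metadata missing for SNPs {missing[:5]} ...")
    aligned = indexed.loc[snp_map.names, ["call_rate", "gentrain"]].reset_index()
    aligned.columns = ["snp_name", "call_rate", "gentrain"]
    return aligned


# ---------------------------------------------------------------------------
# sample sheets


def read_sample_sheet(source) -> list[tuple[str, str]]:
    """Normalize a sample sheet (CSV path, DataFrame or iterable of pairs)."""
    if isinstance(source, pd.DataFrame):
        df = source
    elif isinstance(source, (str, Path)):
        df = pd.read_csv(source, dtype=str)
    else:
        df = pd.DataFrame(list(source), columns=["sample_id", "status"])
    cols = {c.lower().replace(" ", "_"): c for c in df.columns}
    if "sample_id" not in cols or "status" not in cols:
        if df.shape[1] >= 2:
            df = df.iloc[:, :2]
            df.columns = ["sample_id", "status"]
        else:
            raise ValueError("sample sheet needs sample_id and status columns")
    else:
        df = df[[cols["sample_id"], cols["status"]]]
        df.columns = ["sample_id", "status"]
    pairs = [(str(r.sample_id), str(r.status).strip().lower()) for r in df.itertuples()]
    bad = {s for _, s in pairs} - set(STATUSES)
    if bad:
        raise ValueError(f"unknown status values {sorted(bad)}; allowed: {STATUSES}")
    dup = pd.Series([p[0] for p in pairs]).duplicated()
    if dup.any():
        raise ValueError(f"duplicate sample id {pairs[int(dup.idxmax())][0]!r}")
    return pairs


def write_sample_sheet(m: GenotypeMatrix, path) -> None:
    pd.DataFrame({"sample_id": m.sample_ids, "status": m.statuses}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# genotype reports


def _norm_header(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


_LONG_COLUMNS = {
    "sample": {"sampleid", "sample"},
    "snp": {"snpname", "snp"},
    "a1": {"allele1ab", "allele1"},
    "a2": {"allele2ab", "allele2"},
    "gentrain": {"gentrainscore", "gcscore", "gentrain"},
}


def _code_pair(a1: str, a2: str) -> int:
    a1, a2 = a1.strip().upper(), a2.strip().upper()
    if a1 in NOCALL_TOKENS or a2 in NOCALL_TOKENS:
        return NOCALL
    if a1 not in "AB" or a2 not in "AB":
        raise ValueError(f"unrecognized allele pair ({a1!r}, {a2!r})")
    if a1 == a2:
        return HOM_A if a1 == "A" else HOM_B
    return HET


def _code_cell(cell: str) -> int:
    cell = str(cell).strip().upper()
    if cell in NOCALL_TOKENS or cell in {"——", "—"}:
        return NOCALL
    if len(cell) != 2:
        raise ValueError(f"unrecognized genotype cell {cell!r}")
    return _code_pair(cell[0], cell[1])


def read_genotypes(
    path,
    snp_map: SnpMap,
    samples,
    *,
    dialect: str = "long",
    sep: str | None = None,
) -> GenotypeMatrix:
    """Join a genotype report to the map; absent cells become no-calls.

    ``dialect`` is "long" (GenomeStudio-like final report) or "matrix"
    (samples x SNPs CSV).  SNPs in the report that are missing from the map
    raise, listing the unknown names; duplicate (sample, SNP) rows raise.
    Report rows for samples not in the sheet are ignored: the sheet defines
    the cohort.
    """
    pairs = read_sample_sheet(samples)
    sample_ids = [p[0] for p in pairs]
    statuses = [p[1] for p in pairs]
    n, p = len(sample_ids), len(snp_map)
    calls = np.full((n, p), NOCALL, dtype=np.int8)
    qc = None

    if dialect == "long":
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                         dtype=str, keep_default_na=False)
        norm = {_norm_header(c): c for c in df.columns}
        resolved = {}
        for key, aliases in _LONG_COLUMNS.items():
            for alias in aliases:
                if alias in norm:
                    resolved[key] = norm[alias]
                    break
        for key in ("sample", "snp", "a1", "a2"):
            if key not in resolved:
                raise ValueError(f"long report missing a recognizable {key} column")
        snp_col = df[resolved["snp"]].astype(str)
        name_to_index = {name: i for i, name in enumerate(snp_map.names)}
        unknown = sorted(set(snp_col) - set(name_to_index))
        if unknown:
            raise ValueError(f"report contains SNPs not in map: {unknown[:10]}")
        ci = snp_col.map(name_to_index).to_numpy(np.int64)
        sample_index = {s: i for i, s in enumerate(sample_ids)}
        si = df[resolved["sample"]].astype(str).map(sample_index)
        known = si.notna().to_numpy()
        si = si.fillna(-1).to_numpy(np.int64)

        a1 = df[resolved["a1"]].astype(str).str.strip().str.upper()
        a2 = df[resolved["a2"]].astype(str).str.strip().str.upper()
        missing = a1.isin(NOCALL_TOKENS) | a2.isin(NOCALL_TOKENS)
        valid = a1.isin(["A", "B"]) & a2.isin(["A", "B"])
        bad = ~missing & ~valid
        if bad.any():
            k = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"unrecognized allele pair ({a1.iat[k]!r}, {a2.iat[k]!r})")
        codes = np.full(len(df), NOCALL, dtype=np.int8)
        both_a = (a1 == "A") & (a2 == "A")
        both_b = (a1 == "B") & (a2 == "B")
        called = (valid & ~missing).to_numpy()
        codes[(called & both_a.to_numpy())] = HOM_A
        codes[(called & both_b.to_numpy())] = HOM_B
        codes[(called & ~(both_a | both_b).to_numpy())] = HET

        keys = si[known] * p + ci[known]
        uniq, counts = np.unique(keys, return_counts=True)
        if (counts > 1).any():
            key = int(uniq[counts > 1][0])
            raise ValueError(
                f"duplicate row for sample {sample_ids[key // p]!r}, "
                f"SNP {snp_map.names[key % p]!r}"
            )
        calls[si[known], ci[known]] = codes[known]

        if "gentrain" in resolved:
            gt = pd.to_numeric(df[resolved["gentrain"]], errors="coerce")
            per_snp = pd.DataFrame({"ci": ci, "gt": gt}).groupby("ci")["gt"].first()
            if per_snp.notna().all() and len(per_snp) == p:
                matrix = GenotypeMatrix(sample_ids, statuses, calls, snp_map)
                qc = pd.DataFrame(
                    {
                        "snp_name": snp_map.names,
                        "call_rate": matrix.call_rates(),
                        "gentrain": per_snp.sort_index().to_numpy(),
                    }
                )
    elif dialect == "matrix":
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                         dtype=str, keep_default_na=False, index_col=0)
        unknown = sorted(set(df.columns) - set(snp_map.names))
        if unknown:
            raise ValueError(f"report contains SNPs not in map: {unknown[:10]}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate row for sample {dup!r}")
        sample_index = {s: i for i, s in enumerate(sample_ids)}
        for snp in df.columns:
            ci = snp_map.index_of(snp)
            for sid, cell in df[snp].items():
                si = sample_index.get(str(sid))
                if si is not None:
                    calls[si, ci] = _code_cell(cell)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'long' or 'matrix'")

    return GenotypeMatrix(sample_ids, statuses, calls, snp_map, qc)


def write_genotypes_long(m: GenotypeMatrix, path, *, gentrain: bool = True) -> None:
    """Write a GenomeStudio-like long-format report (one row per sample x SNP)."""
    n, p = m.calls.shape
    names = m.snp_map.names
    a1 = np.array(["A", "A", "B", "-"])
    a2 = np.array(["A", "B", "B", "-"])
    frame = pd.DataFrame(
        {
            "Sample ID": np.repeat(m.sample_ids, p),
            "SNP Name": np.tile(names, n),
            "Allele1 - AB": a1[m.calls.ravel()],
            "Allele2 - AB": a2[m.calls.ravel()],
        }
    )
    if gentrain and m.qc is not None:
        frame["GenTrain Score"] = np.tile(m.qc["gentrain"].to_numpy(), n)
    frame.to_csv(path, index=False)


def write_qc(m: GenotypeMatrix, path) -> None:
    if m.qc is None:
        raise ValueError("matrix has no QC metadata")
    m.qc.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QC filter and status split


def apply_qc(
    m: GenotypeMatrix,
    min_call_rate: float = 0.80,
    min_gentrain: float = 0.25,
) -> GenotypeMatrix:
    """Drop SNPs failing chip QC; keep every sample; re-index contiguously.

    A SNP survives iff call_rate > ``min_call_rate`` (strict, matching the
    ">80%" wording) and gentrain >= ``min_gentrain`` (inclusive minimum).
    No allele-frequency filter is applied.  Idempotent for fixed thresholds.
    """
    if m.qc is None:
        raise ValueError(
            "no per-SNP QC metadata attached; attach_qc() first or skip QC explicitly"
        )
    call_rate = m.qc["call_rate"].to_numpy(float)
    gentrain = m.qc["gentrain"].to_numpy(float)
    keep = (call_rate > min_call_rate) & (gentrain >= min_gentrain)
    n_cr = int((~(call_rate > min_call_rate)).sum())
    n_gt = int((~(gentrain >= min_gentrain)).sum())
    logger.info(
        "QC removed %d/%d SNPs (%d failing call rate <= %.3g, %d failing GenTrain < %.3g)",
        int((~keep).sum()), len(keep), n_cr, min_call_rate, n_gt, min_gentrain,
    )
    return m.subset_snps(keep)


def split_by_status(
    m: GenotypeMatrix,
) -> tuple[GenotypeMatrix, GenotypeMatrix, GenotypeMatrix]:
    """Partition samples into (affected, carrier, normal) sub-matrices.

    The SNP axis is untouched.  At least one affected sample is required
    because the consensus scan is undefined without cases.
    """
    groups = {"affected": [], "carrier": [], "normal": []}
    for i, status in enumerate(m.statuses):
        if status in groups:
            groups[status].append(i)
    if not groups["affected"]:
        raise ValueError("no affected samples; the homozygosity scan is undefined")
    return (
        m.subset_samples(groups["affected"]),
        m.subset_samples(groups["carrier"]),
        m.subset_samples(groups["normal"]),
    )
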