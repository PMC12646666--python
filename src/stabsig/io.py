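"""Domain containers and tabular readers/writers shared across the pipeline.

Conventions: genes are rows and samples are columns everywhere; all tables
are tab-delimited UTF-8 with '.' as the decimal mark; missing outcome values
are written as empty string or ``NA`` and held internally as NaN, never 0.
Identifier matching between counts and metadata is exact-string.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

ARMS = {"treated", "placebo", "control"}
RESPONSES = {"R", "NR", "unknown"}
DIRECTIONS = {"positive", "negative"}

#: Optional real-valued outcome / covariate columns of a metadata table.
OUTCOME_COLUMNS = (
    "cpep_auc_pct_baseline_m6",
    "cpep_auc_pct_baseline_m12",
    "time_to_diagnosis",
    "age",
)


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates its contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), integer dtype

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            if not np.all(np.isfinite(as_float)):
                bad = np.argwhere(~np.isfinite(as_float))[0]
                raise ValidationError(
                    f"non-finite count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            rounded = np.rint(as_float)
            if not np.array_equal(rounded, as_float):
                bad = np.argwhere(rounded != as_float)[0]
                raise ValidationError(
                    f"non-integer count {as_float[tuple(bad)]!r} at gene "
                    f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = rounded.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count {self.counts[tuple(bad)]} at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            [self.gene_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.gene_ids[i] for i in keep],
            list(self.sample_ids),
            self.counts[keep],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])


@dataclass
class NormalizedMatrix:
    """Genes x samples matrix of depth-normalized expression values.

    ``values[g, j] = counts[g, j] / size_factors[j]`` when produced by the
    normalization stage; any non-negative real matrix (e.g. log-transformed)
    is accepted so downstream stages can share the container.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("values shape does not match identifier lists")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if self.size_factors.shape != (len(self.sample_ids),):
                raise ValidationError("one size factor per sample required")
            if np.any(self.size_factors <= 0):
                raise ValidationError("size factors must be > 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSignature:
    """Ordered gene set with per-gene statistic and provenance.

    ``direction`` records whether the genes mark the responder ("positive")
    or nonresponder ("negative") side of the outcome axis. ``entries`` is a
    DataFrame with columns gene_id, statistic, p_value, adjusted_p (NaN when
    no multiplicity correction applies), ordered by the deriving operation's
    ranking.
    """

    name: str
    direction: Literal["positive", "negative"]
    entries: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "statistic", "p_value", "adjusted_p"]))

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(
                f"direction must be one of {sorted(DIRECTIONS)}, got {self.direction!r}"
            )
        required = ["gene_id", "statistic", "p_value", "adjusted_p"]
        for col in required:
            if col not in self.entries.columns:
                if col == "adjusted_p":
                    self.entries = self.entries.assign(adjusted_p=np.nan)
                else:
                    raise ValidationError(f"signature entries missing column {col!r}")
        self.entries = self.entries[required].reset_index(drop=True)
        _check_unique(list(self.entries["gene_id"]), "signature gene")
        p = self.entries["p_value"].to_numpy(dtype=float)
        if len(p) and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
            raise ValidationError("p_value outside [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries["gene_id"])

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a genes x samples count matrix.

    ``tsv``: header row of sample ids, first column gene ids.
    ``mtx-triplet``: MatrixMarket coordinate file ``<stem>.mtx`` with sidecar
    ``<stem>.genes.txt`` and ``<stem>.samples.txt`` id files (one per line).
    """
    path = Path(path)
    if format == "tsv":
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy()
        if values.dtype == object:
            raise ValidationError(f"{path}: non-numeric entries in count matrix")
        return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)
    if format == "mtx-triplet":
        mtx = path if path.suffix == ".mtx" else path.with_suffix(".mtx")
        if not mtx.exists():
            raise FileNotFoundError(mtx)
        stem = mtx.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        mat = scipy.io.mmread(mtx)
        return CountMatrix(genes, samples, np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat))
    raise ValueError(f"unknown count-matrix format {format!r}")


def write_count_matrix(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        cm.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")
    elif format == "mtx-triplet":
        mtx = path if path.suffix == ".mtx" else path.with_suffix(".mtx")
        stem = mtx.with_suffix("")
        scipy.io.mmwrite(mtx, scipy.sparse.coo_matrix(cm.counts), field="integer")
        Path(f"{stem}.genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        Path(f"{stem}.samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata table (TSV, one row per sample).

    Required columns: sample_id, study, arm. Optional: response, batch, sex
    and the real-valued outcome columns. Unparseable outcome cells become
    NaN; their count is logged as a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "study", "arm"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")
    bad_arm = set(df["arm"]) - ARMS
    if bad_arm:
        raise ValidationError(f"{path}: unknown arm value(s) {sorted(bad_arm)}")
    if "response" not in df.columns:
        df["response"] = "unknown"
    df.loc[df["response"] == "", "response"] = "unknown"
    bad_resp = set(df["response"]) - RESPONSES
    if bad_resp:
        raise ValidationError(f"{path}: unknown response value(s) {sorted(bad_resp)}")
    n_unparseable = 0
    for col in OUTCOME_COLUMNS:
        if col in df.columns:
            raw = df[col].replace({"": None, "NA": None})
            parsed = pd.to_numeric(raw, errors="coerce")
            n_unparseable += int((parsed.isna() & raw.notna()).sum())
            df[col] = parsed
        else:
            df[col] = np.nan
    if "batch" not in df.columns:
        df["batch"] = "batch0"
    if "sex" not in df.columns:
        df["sex"] = ""
    if n_unparseable:
        warnings.warn(f"{path}: {n_unparseable} unparseable outcome cell(s) set to missing")
        logger.warning("%s: %d unparseable outcome cells", path, n_unparseable)
    df.attrs["n_unparseable_outcomes"] = n_unparseable
    return df.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(path, sep="\t", index=False, na_rep="NA")


_SIG_COLUMNS = ["name", "direction", "gene_id", "rank", "statistic", "p_value", "adjusted_p"]


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    """Write a signature as TSV (one row per gene, rank column 1-based)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = sig.entries.copy()
    df.insert(0, "name", sig.name)
    df.insert(1, "direction", sig.direction)
    df.insert(3, "rank", np.arange(1, len(df) + 1))
    df[_SIG_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_signature(path: str | Path) -> GeneSignature:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "direction": str, "gene_id": str})
    missing = set(_SIG_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing signature column(s) {sorted(missing)}")
    if len(df) == 0:
        # header-only file: name/direction carried in a sidecar-free convention is
        # impossible, so an empty signature reads back with a generic identity
        return GeneSignature(name=path.stem, direction="positive")
    directions = set(df["direction"])
    if not directions <= DIRECTIONS:
        raise ValidationError(
            f"{path}: direction must be in {sorted(DIRECTIONS)}, got {sorted(directions)}")
    if len(directions) != 1 or df["name"].nunique() != 1:
        raise ValidationError(f"{path}: signature file must hold exactly one signature")
    df = df.sort_values("rank", kind="stable")
    return GeneSignature(
        name=str(df["name"].iloc[0]),
        direction=str(df["direction"].iloc[0]),
        entries=df[["gene_id", "statistic", "p_value", "adjusted_p"]],
    )


def align_counts_metadata(cm: CountMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Return metadata reordered to the count matrix columns.

    Every sample in the matrix must have exactly one metadata row.
    """
    lookup = meta.set_index("sample_id")
    missing = [s for s in cm.sample_ids if s not in lookup.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing[:5]}")
    out = lookup.loc[cm.sample_ids].reset_index()
    return out
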