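"""Marker quality control, imputation and the genomic relationship matrix.

SNP genotypes are held as diploid alternate-allele dosages (0/1/2) with
NaN marking missing calls.  The standard curation pipeline is

    qc_filter  ->  impute_missing  ->  grm_vanraden

i.e. drop markers with excess missingness, then rare markers; fill the
remaining gaps by sampling the marginal genotype distribution at each
marker; and build the VanRaden genomic relationship matrix

    G = W W' / (2 * sum_j p_j (1 - p_j)),   w_ij = x_ij - 2 p_j,

where p_j is the allele frequency estimated from non-missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "KinshipMatrix",
    "QCReport",
    "allele_frequencies",
    "qc_filter",
    "impute_missing",
    "grm_vanraden",
    "read_marker_csv",
    "read_vcf_dosage",
    "write_kinship_csv",
    "read_kinship_csv",
]

_VALID_DOSAGES = (0.0, 1.0, 2.0)


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")


@dataclass
class MarkerMatrix:
    """Lines x markers dosage matrix; NaN encodes a missing genotype."""

    values: np.ndarray
    line_ids: np.ndarray
    marker_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("marker matrix must be 2-D (lines x markers)")
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        _check_unique(self.line_ids, "line")
        _check_unique(self.marker_ids, "marker")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, _VALID_DOSAGES).all():
            bad = finite[~np.isin(finite, _VALID_DOSAGES)]
            raise ValueError(f"dosage values outside {{0,1,2}}: {bad[:5]}")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class KinshipMatrix:
    """Symmetric PSD line-by-line relationship matrix."""

    values: np.ndarray
    line_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square and match line_ids")
        _check_unique(self.line_ids, "line")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric within 1e-10")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def reorder(self, line_ids) -> "KinshipMatrix":
        """Return a copy with rows/columns in the order of ``line_ids``."""
        idx = pd.Index(self.line_ids).get_indexer(np.asarray(line_ids, dtype=object))
        if (idx < 0).any():
            missing = np.asarray(line_ids, dtype=object)[idx < 0]
            raise KeyError(f"lines absent from kinship matrix: {missing[:5]}")
        return KinshipMatrix(self.values[np.ix_(idx, idx)], np.asarray(line_ids, dtype=object))


@dataclass
class QCReport:
    n_markers_in: int
    n_removed_maf: int
    n_removed_missing: int
    n_markers_out: int
    maf_threshold: float
    missing_threshold: float
    removed_marker_ids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_markers_out != self.n_markers_in - self.n_removed_maf - self.n_removed_missing:
            raise ValueError("QC counts are inconsistent")


def allele_frequencies(m: MarkerMatrix) -> np.ndarray:
    """Per-marker allele frequency from non-missing dosages.

    p_j = sum(non-missing dosages at j) / (2 * number of non-missing calls).
    Raises if a marker has no non-missing call.
    """
    obs = ~np.isnan(m.values)
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = m.marker_ids[n_obs == 0]
        raise ValueError(f"markers entirely missing: {list(bad[:5])}")
    totals = np.nansum(m.values, axis=0)
    return totals / (2.0 * n_obs)


def qc_filter(
    m: MarkerMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.50,
) -> tuple[MarkerMatrix, QCReport]:
    """Drop markers with excess missingness, then markers with low MAF.

    A marker is removed if its fraction of missing calls is strictly greater
    than ``missing_max``, or (among survivors) its minor allele frequency,
    computed on the non-missing calls, is strictly below ``maf_min``.  Each
    marker is counted under one removal reason only, missingness first.
    """
    if not (0.0 < maf_min <= 0.5):
        raise ValueError("maf_min must be in (0, 0.5]")
    if not (0.0 < missing_max < 1.0):
        raise ValueError("missing_max must be in (0, 1)")

    miss_frac = np.isnan(m.values).mean(axis=0)
    # Entirely-missing markers cannot yield an allele frequency but always
    # exceed any missing_max < 1, so they fall under the missingness rule.
    drop_missing = miss_frac > missing_max
    keep1 = ~drop_missing

    survivors = MarkerMatrix(m.values[:, keep1], m.line_ids, m.marker_ids[keep1])
    if survivors.n_markers == 0:
        raise ValueError("all markers removed by the missingness filter")
    p = allele_frequencies(survivors)
    maf = np.minimum(p, 1.0 - p)
    drop_maf = maf < maf_min
    keep2 = ~drop_maf

    out = MarkerMatrix(
        survivors.values[:, keep2], survivors.line_ids, survivors.marker_ids[keep2]
    )
    if out.n_markers == 0:
        raise ValueError("all markers removed by QC")
    report = QCReport(
        n_markers_in=m.n_markers,
        n_removed_maf=int(drop_maf.sum()),
        n_removed_missing=int(drop_missing.sum()),
        n_markers_out=out.n_markers,
        maf_threshold=maf_min,
        missing_threshold=missing_max,
        removed_marker_ids={
            "missing": list(m.marker_ids[drop_missing]),
            "maf": list(survivors.marker_ids[drop_maf]),
        },
    )
    return out, report


def impute_missing(
    m: MarkerMatrix, seed: int, impute_model: str = "binomial2"
) -> MarkerMatrix:
    """Fill missing dosages by sampling the marginal genotype distribution.

    With ``impute_model="binomial2"`` (default) each missing cell at marker j
    is drawn as Binomial(2, p_j), preserving the diploid 0/1/2 coding; with
    ``"bernoulli"`` the draw is Bernoulli(p_j) on the 0/1 scale.  p_j is the
    allele frequency estimated from the marker's non-missing calls.
    Non-missing cells are untouched and the draw is reproducible per seed.
    """
    if impute_model not in ("binomial2", "bernoulli"):
        raise ValueError("impute_model must be 'binomial2' or 'bernoulli'")
    p = allele_frequencies(m)
    rng = np.random.default_rng(seed)
    values = m.values.copy()
    miss = np.isnan(values)
    rows, cols = np.nonzero(miss)
    n_trials = 2 if impute_model == "binomial2" else 1
    values[rows, cols] = rng.binomial(n_trials, p[cols]).astype(float)
    return MarkerMatrix(values, m.line_ids, m.marker_ids)


def grm_vanraden(m: MarkerMatrix, psd_tol: float = 1e-8) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from a complete dosage matrix.

    G = W W' / (2 * sum_j p_j (1-p_j)) with W the column-centered matrix
    (w_ij = x_ij - 2 p_j).  Requires at least two polymorphic markers.  A
    tiny negative minimum eigenvalue (> -psd_tol) is repaired with a
    psd_tol * I jitter; anything more negative raises.
    """
    if np.isnan(m.values).any():
        raise ValueError("marker matrix contains missing values; impute first")
    p = allele_frequencies(m)
    het = p * (1.0 - p)
    if (het > 0).sum() < 2:
        raise ValueError("need at least two polymorphic markers")
    denom = 2.0 * het.sum()
    if denom <= 0:
        raise ValueError("all markers monomorphic; VanRaden denominator is zero")
    w = m.values - 2.0 * p
    g = (w @ w.T) / denom
    g = 0.5 * (g + g.T)
    min_eig = float(np.linalg.eigvalsh(g)[0])
    if min_eig < -psd_tol:
        raise ValueError(f"G is not PSD (min eigenvalue {min_eig:.3e})")
    if min_eig < 0:
        g = g + psd_tol * np.eye(g.shape[0])
    return KinshipMatrix(g, m.line_ids)


# ---------------------------------------------------------------------------
# I/O


def read_marker_csv(path, sep: str = ",") -> MarkerMatrix:
    """Read a dosage CSV/TSV: first column line ID, header = marker IDs."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return MarkerMatrix(
        df.to_numpy(dtype=float),
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
    )


def read_vcf_dosage(path) -> MarkerMatrix:
    """Read a diploid VCF into alternate-allele dosages (requires cyvcf2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF input requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    line_ids = np.asarray(vcf.samples, dtype=object)
    cols, marker_ids = [], []
    for var in vcf:
        gts = np.asarray(var.genotype.array())[:, :2].astype(float)
        gts[gts < 0] = np.nan
        dosage = gts.sum(axis=1)
        cols.append(dosage)
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    values = np.column_stack(cols) if cols else np.empty((len(line_ids), 0))
    return MarkerMatrix(values, line_ids, np.asarray(marker_ids, dtype=object))


def write_kinship_csv(k: KinshipMatrix, path) -> None:
    pd.DataFrame(k.values, index=k.line_ids, columns=k.line_ids).to_csv(path)


def read_kinship_csv(path) -> KinshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return KinshipMatrix(df.to_numpy(dtype=float), df.index.to_numpy(dtype=object))
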