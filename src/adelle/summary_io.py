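"""Reading and writing Z-score matrices, annotations and trans masks.

A study is a D̃×M matrix of per-trait, per-SNP association Z scores (traits
as rows).  Formats: tab-delimited text with a header row of SNP ids and a
first column of trait ids, or an HDF5 layout with datasets
``values``/``trait_ids``/``snp_ids``.  Which allele a Z score is oriented to
is irrelevant downstream (everything uses |Z| or Z²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ZMatrix",
    "FeatureAnnotation",
    "TransMask",
    "load_z_matrix",
    "save_z_matrix",
    "z_from_t",
    "z_from_lrt",
    "build_trans_mask",
]


@dataclass
class ZMatrix:
    """D̃×M association Z scores with trait/SNP identifiers."""

    values: np.ndarray
    trait_ids: list[str]
    snp_ids: list[str]
    n_samples: int | None = None
    n_covariates: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d matrix")
        d, m = self.values.shape
        if d < 1 or m < 1:
            raise ValueError("need at least one trait and one SNP")
        if len(self.trait_ids) != d or len(self.snp_ids) != m:
            raise ValueError("id lengths must match matrix dimensions")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite Z score at trait '{self.trait_ids[i]}', "
                f"SNP '{self.snp_ids[j]}'"
            )

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureAnnotation:
    """Genomic coordinates (1-based) for SNPs or genes."""

    ids: list[str]
    chromosome: np.ndarray
    position: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("feature ids must be unique")
        if np.any(self.position < 0):
            raise ValueError("positions must be nonnegative")
        self._index = {fid: i for i, fid in enumerate(self.ids)}

    @classmethod
    def from_file(cls, path) -> "FeatureAnnotation":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["id", "chromosome", "position"],
                         dtype={"id": str, "chromosome": str})
        return cls(ids=df["id"].tolist(), chromosome=df["chromosome"].to_numpy(),
                   position=df["position"].to_numpy())

    def lookup(self, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise KeyError(f"features missing from annotation: {missing[:5]}")
        idx = np.array([self._index[i] for i in ids])
        return self.chromosome[idx], self.position[idx]


@dataclass
class TransMask:
    """Per-SNP boolean membership in 𝒟_m; shape (M, D̃)."""

    matrix: np.ndarray
    snp_ids: list[str]
    trait_ids: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.snp_ids), len(self.trait_ids)):
            raise ValueError("mask shape must be (M, D)")

    @property
    def counts(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def mask_classes(self) -> dict[bytes, np.ndarray]:
        """Group SNP indices by identical trans set (grid re-use)."""
        classes: dict[bytes, list[int]] = {}
        for i, row in enumerate(self.matrix):
            classes.setdefault(row.tobytes(), []).append(i)
        return {k: np.array(v) for k, v in classes.items()}


def load_z_matrix(path, fmt: str | None = None, *,
                  drop_missing_traits: bool = False,
                  n_samples: int | None = None,
                  n_covariates: int = 0) -> ZMatrix:
    """Load a Z matrix from delimited text or HDF5.

    Text files must parse fully numeric; a missing cell raises unless
    ``drop_missing_traits`` drops the offending trait rows (logged).
    """
    path = Path(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix in {".h5", ".hdf5"} else "text"
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            vals = f["values"][:]
            traits = [t.decode() if isinstance(t, bytes) else str(t)
                      for t in f["trait_ids"][:]]
            snps = [s.decode() if isinstance(s, bytes) else str(s)
                    for s in f["snp_ids"][:]]
            ns = int(f.attrs.get("n_samples", 0)) or n_samples
            nc = int(f.attrs.get("n_covariates", n_covariates))
        return ZMatrix(vals, traits, snps, n_samples=ns, n_covariates=nc)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed Z matrix file {path}: {exc}") from exc
    bad = df.columns[~df.dtypes.map(lambda t: np.issubdtype(t, np.number))]
    if len(bad):
        col = bad[0]
        row = df.index[df[col].map(lambda v: not _is_number(v))][0]
        raise ValueError(f"non-numeric entry at trait '{row}', SNP '{col}'")
    if df.isna().any().any():
        if not drop_missing_traits:
            j = df.columns[df.isna().any(axis=0)][0]
            i = df.index[df[j].isna()][0]
            raise ValueError(
                f"missing value at trait '{i}', SNP '{j}' "
                "(set drop_missing_traits=True to drop such traits)"
            )
        keep = ~df.isna().any(axis=1)
        logger.warning("dropping %d traits with missing values", (~keep).sum())
        df = df.loc[keep]
    return ZMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index],
                   [str(c) for c in df.columns],
                   n_samples=n_samples, n_covariates=n_covariates)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def save_z_matrix(zmat: ZMatrix, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix in {".h5", ".hdf5"} else "text"
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=zmat.values)
            f.create_dataset("trait_ids", data=np.array(zmat.trait_ids, dtype="S"))
            f.create_dataset("snp_ids", data=np.array(zmat.snp_ids, dtype="S"))
            if zmat.n_samples:
                f.attrs["n_samples"] = zmat.n_samples
            f.attrs["n_covariates"] = zmat.n_covariates
        return
    df = pd.DataFrame(zmat.values, index=zmat.trait_ids, columns=zmat.snp_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def z_from_t(t_stats: np.ndarray, df: float) -> np.ndarray:
    """Map t statistics to N(0,1) scale: z = Φ⁻¹(P_t(t; df)), sign preserved.

    Uses the survival function on the appropriate side so large |t| keeps
    precision instead of saturating the cdf.
    """
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    t = np.asarray(t_stats, dtype=float)
    sf = stats.t.sf(np.abs(t), df)
    z = -special.ndtri(np.clip(sf, np.finfo(float).tiny, 0.5))
    return np.sign(t) * z


def z_from_lrt(chisq_stats: np.ndarray, effect_signs: np.ndarray) -> np.ndarray:
    """Signed square root of 1-df likelihood-ratio χ² statistics."""
    chisq = np.asarray(chisq_stats, dtype=float)
    signs = np.asarray(effect_signs)
    if np.any(chisq < 0):
        raise ValueError("chi-square statistics must be nonnegative")
    if not np.all(np.isin(signs, (-1, 1))):
        raise ValueError("effect signs must be -1 or +1")
    return signs * np.sqrt(chisq)


def build_trans_mask(
    snp_annot: FeatureAnnotation,
    gene_annot: FeatureAnnotation,
    snp_ids: list[str],
    trait_ids: list[str],
    cis_window_bp: int | None = None,
) -> TransMask:
    """𝒟_m: traits trans to SNP m.  Default rule: different chromosome; with
    ``cis_window_bp``, same-chromosome genes farther than ±window (closed
    interval) also count as trans.  SNPs with empty 𝒟_m are flagged (their
    mask row is all False; run_scan skips them)."""
    snp_chr, snp_pos = snp_annot.lookup(snp_ids)
    gene_chr, gene_pos = gene_annot.lookup(trait_ids)
    diff_chr = snp_chr[:, None] != gene_chr[None, :]
    if cis_window_bp is None:
        mask = diff_chr
    else:
        far = np.abs(snp_pos[:, None] - gene_pos[None, :]) > cis_window_bp
        mask = diff_chr | far
    empty = ~mask.any(axis=1)
    if empty.any():
        logger.warning("%d SNPs have no trans traits and will be skipped",
                       int(empty.sum()))
    return TransMask(matrix=mask, snp_ids=list(snp_ids), trait_ids=list(trait_ids))
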