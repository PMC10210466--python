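"""Abundance-matrix container and pre-test processing.

The pipeline mirrors standard practice for label-free (MaxLFQ-style)
proteome quantification: log2 normalization, removal of proteins
without sufficient proteotypic-peptide evidence, exclusion of outlying
replicates by within-condition correlation, and minimum-anchored
stochastic imputation of the remaining missing values (missingness in
such data concentrates at low abundance, so draws are centered at the
global observed minimum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

MATRIX_ID_COLUMNS = ("protein_id", "n_proteotypic_peptides")


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensity table with design metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by protein identifier, one column per sample;
        missing entries are NaN. On the ``"raw"`` scale all present
        entries must be strictly positive.
    peptide_counts
        Per-protein proteotypic-peptide count, aligned to the index.
    design
        Series mapping sample name to condition label.
    control
        The reference condition every treatment is compared against.
    scale
        ``"raw"`` or ``"log2"``; tracked so the log transform is applied
        exactly once.
    """

    intensities: pd.DataFrame
    peptide_counts: pd.Series
    design: pd.Series
    control: str = "CTR"
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        missing_design = [s for s in self.intensities.columns if s not in self.design.index]
        if missing_design:
            raise ValueError(f"samples without a condition: {missing_design}")
        self.design = self.design.loc[list(self.intensities.columns)]
        if self.control not in set(self.design):
            raise ValueError(f"control condition {self.control!r} absent from design")
        self.peptide_counts = self.peptide_counts.reindex(self.intensities.index)
        if self.peptide_counts.isna().any():
            raise ValueError("peptide_counts missing for some proteins")
        if self.scale == "raw":
            vals = self.intensities.to_numpy()
            if np.nanmin(vals, initial=np.inf) <= 0:
                raise ValueError("raw intensities must be strictly positive")

    # -- convenience ------------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.design:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, c in self.design.items() if c == condition]

    def n_missing(self) -> int:
        return int(self.intensities.isna().to_numpy().sum())

    def drop_samples(self, names) -> "AbundanceMatrix":
        keep = [s for s in self.samples if s not in set(names)]
        return replace(self,
                       intensities=self.intensities[keep],
                       design=self.design.loc[keep])

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, matrix_path, design_path=None) -> None:
        out = self.intensities.copy()
        out.insert(0, "n_proteotypic_peptides", self.peptide_counts)
        out.index.name = "protein_id"
        out.to_csv(matrix_path, sep="\t")
        if design_path is not None:
            self.design.rename_axis("sample").rename("condition").to_csv(design_path)

    @classmethod
    def from_tsv(cls, matrix_path, design_path, control: str = "CTR",
                 scale: str = "raw") -> "AbundanceMatrix":
        df = pd.read_csv(matrix_path, sep="\t").set_index("protein_id")
        peptides = df.pop("n_proteotypic_peptides")
        design_df = pd.read_csv(design_path)
        design = pd.Series(design_df["condition"].values,
                           index=design_df["sample"].astype(str))
        return cls(intensities=df, peptide_counts=peptides, design=design,
                   control=control, scale=scale)


# ---------------------------------------------------------------------------
# processing operations
# ---------------------------------------------------------------------------

def log2_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform present entries; missing entries stay missing."""
    if matrix.scale != "raw":
        raise ValueError("matrix is already on the log2 scale")
    return replace(matrix, intensities=np.log2(matrix.intensities), scale="log2")


def filter_proteotypic(matrix: AbundanceMatrix, min_peptides: int = 2) -> AbundanceMatrix:
    """Retain proteins with at least ``min_peptides`` proteotypic peptides.

    Two is the conventional evidence floor for confident identification.
    Order is preserved; the removed count is logged.
    """
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    keep = matrix.peptide_counts >= min_peptides
    removed = int((~keep).sum())
    log.info("proteotypic filter removed %d of %d proteins", removed, len(keep))
    return replace(matrix,
                   intensities=matrix.intensities.loc[keep],
                   peptide_counts=matrix.peptide_counts.loc[keep])


def detect_outlier_replicates(matrix: AbundanceMatrix,
                              min_correlation: float = 0.8) -> pd.Series:
    """Flag replicates that do not correlate with their condition peers.

    A replicate is flagged when its *median* Pearson correlation
    (pairwise-complete proteins) with the other replicates of the same
    condition falls below ``min_correlation``. A condition never loses
    all but one replicate: the best two (by median correlation) are
    always kept.

    Returns a boolean Series per sample, True = outlier.
    """
    flags = pd.Series(False, index=matrix.samples)
    for cond in matrix.conditions:
        cols = matrix.samples_for(cond)
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        corr = matrix.intensities[cols].corr(method="pearson")
        med = pd.Series(
            {c: corr.loc[c, [o for o in cols if o != c]].median() for c in cols}
        )
        bad = med < min_correlation
        if (~bad).sum() < 2:  # hard floor: keep best 2
            for c in med.sort_values(ascending=False).index[:2]:
                bad[c] = False
        flags[cols] = bad[cols]
    return flags


class MinimumImputer(TransformerMixin, BaseEstimator):
    """Minimum-anchored stochastic imputation for log2 matrices.

    Missing label-free intensities are predominantly
    missing-not-at-random censoring at the detection limit, so each
    missing entry is replaced by a draw from
    ``Normal(m, sd^2)`` where ``m`` is the global minimum of the present
    log2 values. ``sd`` defaults to 0.3 log2 units; a seed is mandatory
    for reproducibility.

    Attributes
    ----------
    anchor_ : float
        Global minimum of the present values seen in ``fit``.
    n_imputed_ : int
        Number of entries filled by the last ``transform``.
    """

    def __init__(self, sd: float = 0.3, random_state: int = 0):
        self.sd = sd
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.all(np.isnan(X)):
            raise ValueError("cannot impute an entirely missing matrix")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        self.anchor_ = float(np.nanmin(X))
        return self

    def transform(self, X):
        arr = np.array(X, dtype=float, copy=True)
        mask = np.isnan(arr)
        rng = np.random.default_rng(self.random_state)
        # row-major fill order makes the draw sequence deterministic
        arr[mask] = rng.normal(self.anchor_, self.sd, size=int(mask.sum()))
        self.n_imputed_ = int(mask.sum())
        return arr


def impute_min_random(matrix: AbundanceMatrix, sd: float = 0.3,
                      seed: int = 0) -> AbundanceMatrix:
    """Impute missing log2 entries around the global observed minimum."""
    if matrix.scale != "log2":
        raise ValueError("impute_min_random requires a log2-scale matrix")
    imp = MinimumImputer(sd=sd, random_state=seed)
    filled = imp.fit(matrix.intensities.to_numpy()).transform(
        matrix.intensities.to_numpy())
    log.info("imputed %d missing entries around minimum %.3f",
             imp.n_imputed_, imp.anchor_)
    return replace(matrix, intensities=pd.DataFrame(
        filled, index=matrix.intensities.index, columns=matrix.intensities.columns))
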