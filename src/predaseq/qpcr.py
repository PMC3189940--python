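"""Relative quantification of qPCR data by the 2^-ddCt method.

Per gene and sample, replicate Ct values are averaged first; dCt is the
averaged target Ct minus the averaged reference-gene Ct of the same
sample; ddCt subtracts the calibrator sample's dCt; relative abundance is
2^-ddCt (amplification efficiency fixed at 2).  Agreement with
sequencing-based expression estimates is assessed by ordinary least
squares on log10-log10 axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CtTable:
    """Replicate Ct values with a designated reference gene and calibrator.

    ``data`` has columns gene, sample, ct (one row per replicate).
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        required = {"gene", "sample", "ct"}
        if not required <= set(self.data.columns):
            raise ValueError(f"CtTable needs columns {sorted(required)}")
        for sample, grp in self.data.groupby("sample"):
            if self.reference_gene not in set(grp["gene"]):
                raise ValueError(
                    f"reference gene {self.reference_gene!r} missing in sample "
                    f"{sample!r}"
                )
        if self.calibrator_sample not in set(self.data["sample"]):
            raise ValueError(f"calibrator sample {self.calibrator_sample!r} absent")

    @classmethod
    def from_tsv(cls, path: str | Path, reference_gene: str,
                 calibrator_sample: str) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"),
                   reference_gene, calibrator_sample)

    def mean_cts(self) -> pd.DataFrame:
        """Replicate-averaged Ct, genes x samples."""
        return self.data.groupby(["gene", "sample"])["ct"].mean().unstack("sample")


def relative_abundance(table: CtTable) -> pd.DataFrame:
    """Per-gene, per-sample fold values by 2^-ddCt.

    The calibrator sample's column is identically 1 by construction.
    Adding a constant to every Ct of a sample (a plate-wide shift) cancels
    in the reference subtraction and leaves the result unchanged.
    """
    means = table.mean_cts()
    if means.isna().any().any():
        missing = means[means.isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing Ct values for genes {missing}")
    ref = means.loc[table.reference_gene]
    dct = means.sub(ref, axis=1)
    ddct = dct.sub(dct[table.calibrator_sample], axis=0)
    fold = np.power(2.0, -ddct)
    return fold.drop(index=table.reference_gene)


def correlate_with_gei(
    fold_values: Mapping[str, float] | pd.Series,
    gei_values: Mapping[str, float] | pd.Series,
) -> dict:
    """OLS of log10(qPCR fold) on log10(GEI) over paired genes.

    Returns ``r_squared``, ``slope`` and ``intercept``.  All values must be
    positive; at least three paired genes and non-constant GEI required.
    """
    fold = pd.Series(fold_values, dtype=float)
    geis = pd.Series(gei_values, dtype=float)
    genes = fold.index.intersection(geis.index)
    if len(genes) < 3:
        raise ValueError("need at least 3 paired genes")
    x = geis.loc[genes].to_numpy()
    y = fold.loc[genes].to_numpy()
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("non-positive values: log-log fit undefined")
    lx, ly = np.log10(x), np.log10(y)
    if np.allclose(lx, lx[0]):
        raise ValueError("GEI values are constant: zero variance")
    fit = stats.linregress(lx, ly)
    return {
        "r_squared": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": int(len(genes)),
    }


def write_fold_tsv(fold: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# relative abundance by 2^-ddCt, replicates averaged before dCt\n")
        fold.to_csv(fh, sep="\t")
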