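"""Quantification math for qPCR assays.

Lentiviral titering: Ct values are linearized as Xo = E^(-Ct); per titration
volume the mean LV2 Xo is normalized to the mean beta-actin Xo to give a
relative copy number; volume is regressed on relative copy number; the
volume-per-dose (VPD) at the reference virus's relative copy number yields
the titer via titer = cells * MOI / VPD.

Expression analysis: the 2^-ddCt method against a housekeeping gene and a
reference sample, with Welch's unequal-variance t-test for comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class WetlabError(ValueError):
    pass


def xo_from_ct(ct: float | np.ndarray, efficiency: float = 2.0) -> float | np.ndarray:
    """Linearized initial quantity: Xo = efficiency^(-Ct)."""
    if not 1.0 < efficiency <= 2.0:
        raise WetlabError("efficiency must be in (1, 2]")
    ct_arr = np.asarray(ct, dtype=float)
    if not np.all(np.isfinite(ct_arr)):
        raise WetlabError("Ct values must be finite")
    out = efficiency ** (-ct_arr)
    return float(out) if np.isscalar(ct) or ct_arr.ndim == 0 else out


@dataclass
class TitrationFit:
    slope: float  # a in: volume = a * relative copy number + b
    intercept: float
    r_squared: float
    points: list[tuple[float, float]]  # (volume, relative copy number)


@dataclass
class TiterResult:
    vpd: float
    titer: float
    n_cells: int
    moi: float


def fit_titration_curve(
    table: pd.DataFrame,
    lv2_gene: str = "LV2",
    actin_gene: str = "ACTB",
    volumes: list[float] | None = None,
    efficiency: float = 2.0,
) -> TitrationFit:
    """Standard curve of titration volume versus normalized LV2 copy number.

    ``table`` needs columns ``volume``, ``gene``, ``replicate``, ``ct``.
    Per volume: relative copy = mean(Xo of LV2 replicates) / mean(Xo of
    actin replicates). Ordinary least squares of volume on relative copy
    (that orientation gives VPD directly from a copy number).
    """
    lv2_gene, actin_gene = lv2_gene.upper(), actin_gene.upper()
    table = table.copy()
    table["gene"] = table["gene"].astype(str).str.upper()
    if volumes is None:
        volumes = sorted(table["volume"].unique())
    if len(volumes) < 2:
        raise WetlabError("need at least 2 titration volumes")
    points = []
    for v in volumes:
        sub = table[table["volume"] == v]
        lv2_ct = sub.loc[sub["gene"] == lv2_gene, "ct"].to_numpy()
        act_ct = sub.loc[sub["gene"] == actin_gene, "ct"].to_numpy()
        if len(lv2_ct) == 0 or len(act_ct) == 0:
            raise WetlabError(f"volume {v}: missing LV2 or actin replicates")
        lv2_xo = np.mean(xo_from_ct(lv2_ct, efficiency))
        act_xo = np.mean(xo_from_ct(act_ct, efficiency))
        if act_xo == 0:
            raise WetlabError(f"volume {v}: zero actin Xo")
        points.append((float(v), float(lv2_xo / act_xo)))
    copy_numbers = np.array([p[1] for p in points])
    vols = np.array([p[0] for p in points])
    fit = stats.linregress(copy_numbers, vols)
    return TitrationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        points=points,
    )


def compute_titer(
    fit: TitrationFit, ref_relative_copy: float, n_cells: int, moi: float
) -> TiterResult:
    """VPD = a * reference relative copy + b; titer = cells * MOI / VPD."""
    vpd = fit.slope * ref_relative_copy + fit.intercept
    if vpd <= 0:
        raise WetlabError(f"non-positive VPD ({vpd:.4g}): curve extrapolation failure")
    return TiterResult(
        vpd=float(vpd), titer=float(n_cells * moi / vpd), n_cells=n_cells, moi=moi
    )


@dataclass
class FoldChangeRecord:
    gene: str
    sample: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float
    sd: float


def fold_change_ddct(
    table: pd.DataFrame,
    housekeeping: str = "ACTB",
    reference_sample: str = "REFERENCE",
) -> list[FoldChangeRecord]:
    """2^-ddCt relative expression against a housekeeping gene and reference sample.

    dCt = mean Ct(gene) - mean Ct(housekeeping) per sample; ddCt = dCt(sample)
    - dCt(reference); fold = 2^-ddCt. The SD is taken over per-replicate
    fold changes (each replicate's Ct against the sample's mean housekeeping
    Ct).
    """
    housekeeping = housekeeping.upper()
    table = table.copy()
    table["gene"] = table["gene"].astype(str).str.upper()
    samples = list(dict.fromkeys(table["sample"]))
    if reference_sample not in samples:
        raise WetlabError(f"reference sample {reference_sample!r} absent from table")
    hk_mean: dict[str, float] = {}
    for s in samples:
        hk = table.loc[(table["sample"] == s) & (table["gene"] == housekeeping), "ct"]
        if len(hk) == 0:
            raise WetlabError(f"sample {s!r}: housekeeping gene {housekeeping} missing")
        hk_mean[s] = float(hk.mean())

    genes = [g for g in dict.fromkeys(table["gene"]) if g != housekeeping]
    ref_dct = {
        g: float(
            table.loc[
                (table["sample"] == reference_sample) & (table["gene"] == g), "ct"
            ].mean()
        )
        - hk_mean[reference_sample]
        for g in genes
    }
    records = []
    for s in samples:
        for g in genes:
            cts = table.loc[(table["sample"] == s) & (table["gene"] == g), "ct"]
            if len(cts) == 0:
                continue
            if math.isnan(ref_dct[g]):
                raise WetlabError(f"gene {g}: missing in reference sample")
            dct = float(cts.mean()) - hk_mean[s]
            ddct = dct - ref_dct[g]
            rep_folds = 2.0 ** -((cts.to_numpy() - hk_mean[s]) - ref_dct[g])
            records.append(
                FoldChangeRecord(
                    gene=g,
                    sample=s,
                    delta_ct=dct,
                    delta_delta_ct=ddct,
                    fold_change=float(2.0**-ddct),
                    sd=float(np.std(rep_folds, ddof=1)) if len(rep_folds) > 1 else 0.0,
                )
            )
    return records


def welch_ttest(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise WetlabError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.inf, float(len(a) + len(b) - 2), 0.0
    se2 = va / len(a) + vb / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def significance_stars(p: float) -> str:
    """Significance annotation at the 0.05 / 0.01 / 0.001 thresholds."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"
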