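"""Relative qPCR quantification by the 2^-ddCt method.

dCt = mean Ct(target) - mean Ct(reference) within a sample; ddCt subtracts
the calibrator sample's dCt; fold change = 2^-ddCt (amplification efficiency
fixed at 2, the standard ddCt assumption). Technical-replicate SDs are
combined in quadrature and reported as an interval on the fold scale,
[2^-(ddCt+SD), 2^-(ddCt-SD)].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ddct_fold_change", "read_ct_table", "write_fold_table"]

CT_COLUMNS = ["sample", "timepoint", "gene", "replicate", "ct"]


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def write_fold_table(folds: pd.DataFrame, path) -> None:
    folds.to_csv(path, sep="\t", index=False)


def _sample_stats(records: pd.DataFrame, gene: str, sample) -> tuple:
    sub = records[(records["gene"] == gene) & (records["sample"] == sample)]
    if len(sub) == 0:
        raise ValueError(f"gene {gene!r} missing in sample {sample!r}")
    if len(sub) < 2:
        raise ValueError(
            f"gene {gene!r} in sample {sample!r} has {len(sub)} replicate(s); need >= 2"
        )
    ct = sub["ct"].to_numpy(dtype=float)
    return float(ct.mean()), float(ct.std(ddof=1))


def ddct_fold_change(
    records: pd.DataFrame, target: str, reference: str, calibrator
) -> pd.DataFrame:
    """Per-sample fold change of ``target`` relative to ``reference``.

    ``records`` holds one row per technical replicate (columns ``sample``,
    ``timepoint``, ``gene``, ``replicate``, ``ct``). The ``calibrator``
    sample defines fold = 1. Returns a frame with columns ``sample``,
    ``timepoint``, ``ddct``, ``fold``, ``fold_lo``, ``fold_hi``, ``sd_ddct``.
    """
    for colset in (CT_COLUMNS,):
        missing = set(colset) - set(records.columns)
        if missing:
            raise ValueError(f"Ct records missing columns: {sorted(missing)}")
    samples = list(dict.fromkeys(records["sample"]))
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} not present")

    cal_t_mean, cal_t_sd = _sample_stats(records, target, calibrator)
    cal_r_mean, cal_r_sd = _sample_stats(records, reference, calibrator)
    cal_dct = cal_t_mean - cal_r_mean

    rows = []
    for sample in samples:
        t_mean, t_sd = _sample_stats(records, target, sample)
        r_mean, r_sd = _sample_stats(records, reference, sample)
        dct = t_mean - r_mean
        ddct = dct - cal_dct
        sd = float(np.sqrt(t_sd**2 + r_sd**2))
        tp = records.loc[records["sample"] == sample, "timepoint"].iloc[0]
        rows.append(
            {
                "sample": sample,
                "timepoint": tp,
                "ddct": ddct,
                "fold": 2.0 ** (-ddct),
                "fold_lo": 2.0 ** (-(ddct + sd)),
                "fold_hi": 2.0 ** (-(ddct - sd)),
                "sd_ddct": sd,
            }
        )
    return pd.DataFrame(rows)
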