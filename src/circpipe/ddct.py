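"""Relative qPCR quantification: ΔCt, ΔΔCt fold changes and group tests.

Normalizer policies:

* ``spike_housekeeper`` — ΔCt against the mean of the spike-in channel's
  Ct and the housekeeper channel(s) Ct (arithmetic mean of Ct values,
  i.e. geometric mean of linear abundances);
* ``28S`` — ΔCt against the reference rRNA channel.

Fold change between conditions is 2^-(ΔCt_case - ΔCt_control).  Group
comparisons pool technical replicates across samples as individual
observations and use a classical equal-variance two-sample t-test
(Welch available behind a flag).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

NORMALIZER_POLICIES = ("spike_housekeeper", "28S")
REQUIRED_COLUMNS = {"sample", "target", "role", "replicate", "ct"}


def _validate_table(table: pd.DataFrame) -> None:
    missing = REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("Ct values must be finite and > 0")


def _normalizer_roles(policy: str) -> tuple[str, ...]:
    if policy == "spike_housekeeper":
        return ("spike_in", "housekeeper")
    if policy == "28S":
        return ("reference_rRNA",)
    raise ValueError(f"unknown normalizer policy {policy!r}; "
                     f"choose from {NORMALIZER_POLICIES}")


def delta_ct(table: pd.DataFrame, policy: str = "spike_housekeeper",
             per_replicate: bool = False) -> pd.DataFrame:
    """ΔCt per (sample, assay target).

    The normalizer Ct of a sample is the mean over the policy's normalizer
    targets of each target's mean Ct.  Samples missing a required
    normalizer target are excluded with a warning.  With
    ``per_replicate=True`` each technical replicate of the assay target
    yields its own ΔCt row (the pooled-observation convention for group
    testing); otherwise replicates are averaged first.
    """
    _validate_table(table)
    roles = _normalizer_roles(policy)
    rows = []
    for sample, sub in table.groupby("sample", sort=True):
        norm_means = []
        ok = True
        for role in roles:
            chan = sub[sub["role"] == role]
            if chan.empty:
                log.warning("sample %s lacks %s target; excluded", sample, role)
                ok = False
                break
            norm_means.append(chan.groupby("target")["ct"].mean().mean())
        if not ok:
            continue
        norm_ct = float(np.mean(norm_means))
        group = sub["group"].iloc[0] if "group" in sub else ""
        assays = sub[sub["role"] == "assay"]
        for target, tsub in assays.groupby("target", sort=True):
            if per_replicate:
                for r in tsub.itertuples():
                    rows.append({"sample": sample, "group": group, "target": target,
                                 "replicate": r.replicate,
                                 "delta_ct": float(r.ct) - norm_ct})
            else:
                rows.append({"sample": sample, "group": group, "target": target,
                             "delta_ct": float(tsub["ct"].mean()) - norm_ct})
    return pd.DataFrame(rows)


def ddct_fold(delta_ct_case: float, delta_ct_control: float) -> float:
    """Fold change 2^-(ΔCt_case - ΔCt_control)."""
    return float(2.0 ** -(delta_ct_case - delta_ct_control))


def fold_by_group(dct: pd.DataFrame, target: str, case_group: str,
                  control_group: str) -> float:
    """Group-level fold change for one target from a ΔCt table."""
    sub = dct[dct["target"] == target]
    case = sub.loc[sub["group"] == case_group, "delta_ct"]
    control = sub.loc[sub["group"] == control_group, "delta_ct"]
    if case.empty or control.empty:
        raise ValueError(f"missing group data for target {target!r}")
    return ddct_fold(float(case.mean()), float(control.mean()))


def group_compare(values: pd.DataFrame, case_group: str, control_group: str,
                  value_column: str = "delta_ct",
                  test: str = "student") -> dict:
    """Per-group mean ± SEM and a two-sample t-test.

    ``values`` carries one observation per row (samples and technical
    replicates pooled), with 'group' and ``value_column`` columns.
    """
    if test not in ("student", "welch"):
        raise ValueError("test must be 'student' or 'welch'")
    out = {}
    arrays = {}
    for name in (case_group, control_group):
        v = values.loc[values["group"] == name, value_column].to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        arrays[name] = v
        out[name] = {"n": int(len(v)), "mean": float(v.mean()),
                     "sem": float(stats.sem(v))}
    a, b = arrays[case_group], arrays[control_group]
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate: no within-group spread
        same = a.mean() == b.mean()
        tstat, pval = (0.0, 1.0) if same else (np.inf * np.sign(a.mean() - b.mean()), 0.0)
    else:
        tstat, pval = stats.ttest_ind(a, b, equal_var=(test == "student"))
    out["t"] = float(tstat)
    out["p"] = float(pval)
    out["test"] = test
    return out


def ddct_report(table: pd.DataFrame, case_group: str, control_group: str,
                policy: str = "spike_housekeeper", test: str = "student",
                ) -> pd.DataFrame:
    """Fold change and group test per assay target (the qPCR figure logic)."""
    dct_mean = delta_ct(table, policy=policy, per_replicate=False)
    dct_rep = delta_ct(table, policy=policy, per_replicate=True)
    rows = []
    for target in sorted(dct_mean["target"].unique()):
        fold = fold_by_group(dct_mean, target, case_group, control_group)
        cmp = group_compare(dct_rep[dct_rep["target"] == target],
                            case_group, control_group, test=test)
        rows.append({
            "target": target, "fold_change": fold,
            "case_mean_dct": cmp[case_group]["mean"],
            "case_sem": cmp[case_group]["sem"],
            "control_mean_dct": cmp[control_group]["mean"],
            "control_sem": cmp[control_group]["sem"],
            "t": cmp["t"], "p": cmp["p"],
        })
    return pd.DataFrame(rows)
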