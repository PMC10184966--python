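"""Permutation-based Network Comparison Test (NCT) between two groups.

Two statistics are tested by permuting group labels over the pooled rows
(preserving group sizes) and re-estimating both networks each time:

* structure invariance  M = max_{i<j} |w_ij^A - w_ij^B|
* global-strength invariance  S = | sum|w^A| - sum|w^B| |

Per-edge differences are tested against their own permutation distributions
with Holm-Bonferroni correction.  All p-values use the add-one convention
p = (1 + #{perm >= obs}) / (1 + n_perm), so they are never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import SymptomNetError, ValidationError
from .glasso import ebic_glasso

logger = logging.getLogger(__name__)


@dataclass
class NCTResult:
    labels: list[str]
    m_observed: float
    s_observed: float
    p_m: float
    p_s: float
    edge_table: pd.DataFrame  # node_i, node_j, weight_a, weight_b, diff, p_raw, p_holm
    n_perm: int
    seed: int
    edge_family: str = "all"

    def significant_edges(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.edge_table[self.edge_table["p_holm"] < alpha].reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Network Comparison Test",
            f"  permutations: {self.n_perm}  (seed {self.seed})",
            f"  structure invariance   M = {self.m_observed:.4f}   p = {self.p_m:.4f}",
            f"  global strength        S = {self.s_observed:.4f}   p = {self.p_s:.4f}",
            f"  per-edge tests ({self.edge_family} family): "
            f"{int((self.edge_table['p_holm'] < 0.05).sum())} Holm-significant at 0.05",
        ]
        return "\n".join(lines)


def _fit_weights(df: pd.DataFrame, items: list[str], fit_kwargs: dict) -> np.ndarray:
    net, _ = ebic_glasso(df[items], **fit_kwargs)
    return net.weights


def nct(
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    items: list[str] | None = None,
    edge_family: str = "all",
    max_failure_rate: float = 0.05,
    **fit_kwargs,
) -> NCTResult:
    """Run the NCT.  ``edge_family`` controls the Holm family: ``"all"``
    tests every node pair, ``"observed"`` only pairs with a nonzero weight in
    either observed network.  Each (re-)estimation uses its own EBIC-selected
    penalty.  Group sizes must both be >= 50."""
    if items is None:
        items = [c for c in data_a.columns if c in data_b.columns
                 and pd.api.types.is_numeric_dtype(data_a[c])]
    if not items:
        raise ValidationError("nct: no shared numeric item columns")
    if sorted(items) != sorted([c for c in items if c in data_b.columns]):
        raise ValidationError("nct: groups do not share the item set")
    na, nb = len(data_a), len(data_b)
    if na < 50 or nb < 50:
        raise ValidationError("nct: each group needs n >= 50")
    if edge_family not in ("all", "observed"):
        raise ValidationError(f"nct: unknown edge family {edge_family!r}")

    Wa = _fit_weights(data_a, items, fit_kwargs)
    Wb = _fit_weights(data_b, items, fit_kwargs)
    p = len(items)
    iu = np.triu_indices(p, 1)
    diff_obs = np.abs(Wa[iu] - Wb[iu])
    m_obs = float(diff_obs.max())
    s_obs = float(abs(np.abs(Wa[iu]).sum() - np.abs(Wb[iu]).sum()))

    # canonical row order + larger-arm-first assignment make every statistic
    # exactly invariant to swapping the two groups (all stats are |.|)
    pooled = pd.concat([data_a[items], data_b[items]], ignore_index=True)
    arr = pooled.sort_values(by=items, kind="mergesort").reset_index(drop=True)
    n_big = max(na, nb)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    m_ge = 0
    s_ge = 0
    edge_ge = np.zeros(len(diff_obs), dtype=int)
    done = 0
    failures = 0
    while done < n_perm:
        perm = rng.permutation(na + nb)
        try:
            Wpa = _fit_weights(arr.iloc[perm[:n_big]], items, fit_kwargs)
            Wpb = _fit_weights(arr.iloc[perm[n_big:]], items, fit_kwargs)
        except SymptomNetError as e:
            failures += 1
            logger.warning("NCT permutation failed (%s); resampling", e)
            if failures > max_failure_rate * n_perm:
                raise SymptomNetError(
                    f"nct aborted: {failures} estimation failures"
                ) from e
            continue
        d = np.abs(Wpa[iu] - Wpb[iu])
        if d.max() >= m_obs:
            m_ge += 1
        if abs(np.abs(Wpa[iu]).sum() - np.abs(Wpb[iu]).sum()) >= s_obs:
            s_ge += 1
        edge_ge += d >= diff_obs
        done += 1

    p_m = (1.0 + m_ge) / (1.0 + n_perm)
    p_s = (1.0 + s_ge) / (1.0 + n_perm)
    p_edges = (1.0 + edge_ge) / (1.0 + n_perm)

    if edge_family == "observed":
        family = (Wa[iu] != 0.0) | (Wb[iu] != 0.0)
    else:
        family = np.ones(len(diff_obs), dtype=bool)
    p_holm = np.full(len(diff_obs), np.nan)
    if family.any():
        _, adj, *_ = multipletests(p_edges[family], method="holm")
        p_holm[family] = adj

    table = pd.DataFrame(
        {
            "node_i": [items[i] for i in iu[0]],
            "node_j": [items[j] for j in iu[1]],
            "weight_a": Wa[iu],
            "weight_b": Wb[iu],
            "abs_diff": diff_obs,
            "in_family": family,
            "p_raw": p_edges,
            "p_holm": p_holm,
        }
    )
    return NCTResult(
        labels=list(items),
        m_observed=m_obs,
        s_observed=s_obs,
        p_m=float(p_m),
        p_s=float(p_s),
        edge_table=table,
        n_perm=n_perm,
        seed=seed,
        edge_family=edge_family,
    )


AGE_RULE = {"Younger adults": "a", "Older adults": "b"}
SEX_RULE = {"Male": "a", "Female": "b"}


def group_split(
    data: pd.DataFrame, variable: str, rule: dict, min_per_arm: int = 50
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split respondents into two arms by an explicit category -> arm map.

    ``rule`` maps category values to "a" or "b"; rows with missing or
    unmapped categories are excluded (count logged).  An arm smaller than
    ``min_per_arm`` raises, recommending against comparison.
    """
    if variable not in data.columns:
        raise ValidationError(f"group_split: no column {variable!r}")
    arm = data[variable].map(rule)
    dropped = int(arm.isna().sum())
    if dropped:
        logger.info("group_split: excluded %d rows with missing/unmapped %s", dropped, variable)
    a = data[arm == "a"].reset_index(drop=True)
    b = data[arm == "b"].reset_index(drop=True)
    if len(a) < min_per_arm or len(b) < min_per_arm:
        raise ValidationError(
            f"group_split: arm sizes {len(a)}/{len(b)} below {min_per_arm}; "
            "comparison not recommended"
        )
    return a, b


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    _, adj, *_ = multipletests(p, method="holm")
    return adj
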