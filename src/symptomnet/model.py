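"""Model/Results interface for symptom-network estimation.

`SymptomNetworkModel` holds the data and estimation settings;
:meth:`SymptomNetworkModel.fit` runs EBIC-glasso and returns a
:class:`SymptomNetworkResults` carrying the selected network, centrality
indices, diagnostics, and methods for bootstrap stability, covariate
adjustment and reporting.  `NetworkComparison` wraps the permutation NCT the
same way.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import centrality as _centrality
from . import comparison as _comparison
from . import estimation as _estimation
from . import stability as _stability
from .errors import ValidationError
from .glasso import ebic_glasso
from .network import EbicTrace, WeightedNetwork
from .scales import ALL_ITEMS
from .simulate import DEFAULT_COMMUNITIES


class SymptomNetworkModel:
    """A Gaussian graphical model of ordinal symptom items.

    Parameters
    ----------
    data : DataFrame
        One row per respondent; item columns plus optional covariates.
    items : list of str, optional
        Item columns (default: the 14 GAD/PSQI columns present in data).
    communities : dict, optional
        node -> community label (default: anxiety/sleep split of the
        standard items).
    cor_method : {"polychoric", "pearson", "spearman"}
    gamma : float
        EBIC hyperparameter.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        items: list[str] | None = None,
        communities: dict | None = None,
        cor_method: str = "polychoric",
        gamma: float = 0.5,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        missing: str = "pairwise",
    ):
        if items is None:
            items = [c for c in ALL_ITEMS if c in data.columns]
            if not items:
                items = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
        if not items:
            raise ValidationError("SymptomNetworkModel: no item columns found")
        if communities is None:
            communities = {k: v for k, v in DEFAULT_COMMUNITIES.items() if k in items}
            if set(communities) != set(items):
                communities = None
        self.data = data
        self.items = list(items)
        self.communities = communities
        self.cor_method = cor_method
        self.gamma = gamma
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.missing = missing

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "SymptomNetworkModel":
        return cls(data, **kwargs)

    def _fit_kwargs(self) -> dict:
        return dict(
            cor_method=self.cor_method,
            gamma=self.gamma,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            missing=self.missing,
        )

    def fit(self) -> "SymptomNetworkResults":
        net, trace = ebic_glasso(
            self.data[self.items], communities=self.communities, **self._fit_kwargs()
        )
        return SymptomNetworkResults(self, net, trace)


class SymptomNetworkResults:
    """Fitted network with centrality, stability and adjustment methods."""

    def __init__(self, model: SymptomNetworkModel, network: WeightedNetwork, trace: EbicTrace):
        self.model = model
        self.network = network
        self.ebic_trace = trace
        self._centrality: pd.DataFrame | None = None

    # -- estimates ---------------------------------------------------------
    @property
    def weights(self) -> pd.DataFrame:
        return self.network.to_frame()

    @property
    def lambda_(self) -> float:
        return self.network.lambda_

    def edge_frame(self) -> pd.DataFrame:
        return self.network.edge_frame()

    def centrality(self, harmonic_closeness: bool = False, z_scored: bool = False) -> pd.DataFrame:
        if self._centrality is None:
            self._centrality = _centrality.centrality_table(
                self.network,
                data=self.model.data,
                harmonic_closeness=harmonic_closeness,
                z_scored=z_scored,
            )
        return self._centrality

    def rank(self, k: int = 3, by: str = "ei") -> list[str]:
        return _centrality.rank_symptoms(self.centrality(), k, by=by)

    def average_predictability(self) -> float:
        return float(self.centrality()["predictability"].mean())

    # -- uncertainty / stability ------------------------------------------
    def bootstrap(self, B: int = 1000, seed: int = 0, **kw) -> _stability.BootstrapResult:
        fit = {**self.model._fit_kwargs(), **kw}
        return _stability.bootstrap_edges(
            self.model.data[self.model.items], B=B, seed=seed,
            communities=self.model.communities, **fit,
        )

    def case_drop_stability(
        self, statistic: str = "ei", B: int = 250, seed: int = 0, **kw
    ) -> _stability.CsResult:
        fit = {**self.model._fit_kwargs(), **kw}
        return _stability.case_drop_cs(
            self.model.data[self.model.items], statistic=statistic, B=B, seed=seed,
            communities=self.model.communities, **fit,
        )

    # -- covariate adjustment ---------------------------------------------
    def adjusted_for(self, covariates: list[str]) -> "SymptomNetworkResults":
        """Re-estimate after residualizing items on covariates.

        Residuals are continuous, so a polychoric model falls back to
        Pearson correlations for the adjusted fit.
        """
        resid = _estimation.adjust_for_covariates(
            self.model.data, covariates, items=self.model.items
        )
        method = self.model.cor_method
        if method == "polychoric":
            method = "pearson"
        adj_model = SymptomNetworkModel(
            resid,
            items=self.model.items,
            communities=self.model.communities,
            cor_method=method,
            gamma=self.model.gamma,
            n_lambda=self.model.n_lambda,
            lambda_min_ratio=self.model.lambda_min_ratio,
            missing=self.model.missing,
        )
        return adj_model.fit()

    def compare_with(
        self, other: "SymptomNetworkResults", paired: bool = True
    ) -> _estimation.AdjustedComparison:
        return _estimation.compare_adjusted(self.network, other.network, paired=paired)

    # -- reporting ---------------------------------------------------------
    def summary(self, k: int = 4) -> str:
        net = self.network
        lines = [
            "Symptom network (EBIC-glasso)",
            f"  nodes: {net.p}   edges: {net.edge_count}   "
            f"lambda: {net.lambda_:.4f}   gamma: {net.gamma}   EBIC: {net.ebic:.1f}",
            f"  correlation input: {self.model.cor_method} (missing={self.model.missing})",
        ]
        w = net.upper_triangle()
        if net.edge_count:
            lines.append(
                f"  edge weights range: {w.min():+.3f} .. {w.max():+.3f}"
            )
        tab = self.centrality()
        top_ei = _centrality.rank_symptoms(tab, k, by="ei")
        lines.append(f"  top EI symptoms: {', '.join(top_ei)}")
        if "bridge_ei" in tab.columns:
            top_bei = _centrality.rank_symptoms(tab, k, by="bridge_ei")
            lines.append(f"  top bridge-EI symptoms: {', '.join(top_bei)}")
        if "predictability" in tab.columns:
            lines.append(f"  average predictability: {tab['predictability'].mean():.3f}")
        return "\n".join(lines)


class NetworkComparison:
    """Permutation comparison of the networks of two respondent groups."""

    def __init__(
        self,
        data_a: pd.DataFrame,
        data_b: pd.DataFrame,
        items: list[str] | None = None,
        edge_family: str = "all",
        **fit_kwargs,
    ):
        self.data_a = data_a
        self.data_b = data_b
        self.items = items
        self.edge_family = edge_family
        self.fit_kwargs = fit_kwargs

    @classmethod
    def from_grouping(
        cls, data: pd.DataFrame, variable: str, rule: dict, **kwargs
    ) -> "NetworkComparison":
        a, b = _comparison.group_split(data, variable, rule)
        return cls(a, b, **kwargs)

    def fit(self, n_perm: int = 1000, seed: int = 0) -> _comparison.NCTResult:
        return _comparison.nct(
            self.data_a,
            self.data_b,
            n_perm=n_perm,
            seed=seed,
            items=self.items,
            edge_family=self.edge_family,
            **self.fit_kwargs,
        )
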