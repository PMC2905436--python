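"""Scikit-learn style estimators over the network-analysis primitives.

`DifferentialExpressionFilter` is a supervised feature selector: fitted
on a samples x genes matrix with treatment labels, it keeps the union of
the per-treatment DE signatures.  `WGCNA` is an unsupervised clusterer
of genes (the features): fitted on a samples x genes matrix it builds
the soft-thresholded co-expression network, the topological overlap
matrix, the module dendrogram and the colour-labelled module
assignment, and ranks intramodular hub genes.  Both follow the sklearn
estimator contract (get_params/set_params, trailing-underscore fitted
attributes, input validation) and compose with sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import de, hubs, network
from .modules import GREY, average_linkage, assign_colors, dissimilarity, dynamic_tree_cut

__all__ = ["DifferentialExpressionFilter", "WGCNA"]


def _to_expr_frame(X, feature_names=None) -> pd.DataFrame:
    """Samples x genes input -> genes x samples DataFrame."""
    if isinstance(X, pd.DataFrame):
        return X.T.copy()
    X = check_array(X, dtype=float)
    names = feature_names or [f"g{i:05d}" for i in range(X.shape[1])]
    return pd.DataFrame(X.T, index=list(names),
                        columns=[f"s{i:03d}" for i in range(X.shape[0])])


class DifferentialExpressionFilter(BaseEstimator, TransformerMixin):
    """Select genes differentially expressed in any treatment vs control.

    Parameters mirror the three joint DE criteria: fold change of group
    means >= ``fc_up`` or <= ``fc_down``, t-test p <= ``p_max`` and
    absolute mean difference >= ``min_abs_diff``.  ``fit`` expects
    ``X`` of shape (n_samples, n_genes) and ``y`` a vector of treatment
    labels, one of which is the control label.

    Attributes
    ----------
    signatures_ : dict of treatment -> SignatureList
    union_genes_ : set of selected gene names
    support_ : boolean mask over the input genes
    """

    def __init__(
        self,
        fc_up: float = 1.2,
        fc_down: float = 0.83,
        p_max: float = 0.05,
        min_abs_diff: float = 10.0,
        equal_var: bool = False,
        log2_input: bool = False,
        control_label: str = "control",
    ):
        self.fc_up = fc_up
        self.fc_down = fc_down
        self.p_max = p_max
        self.min_abs_diff = min_abs_diff
        self.equal_var = equal_var
        self.log2_input = log2_input
        self.control_label = control_label

    def _criteria(self) -> de.SignatureCriteria:
        return de.SignatureCriteria(
            fc_up=self.fc_up, fc_down=self.fc_down, p_max=self.p_max,
            min_abs_diff=self.min_abs_diff, log2_input=self.log2_input,
        )

    def fit(self, X, y):
        expr = _to_expr_frame(X)
        y = np.asarray(y)
        if y.shape[0] != expr.shape[1]:
            raise ValueError("y must hold one treatment label per sample")
        if self.control_label not in set(y):
            raise ValueError(f"no {self.control_label!r} samples in y")
        design = pd.DataFrame({"sample_id": expr.columns, "treatment": y})
        criteria = self._criteria()
        self.signatures_ = {}
        for trt in sorted(set(y) - {self.control_label}):
            self.signatures_[trt] = de.compute_signature(
                expr, design, trt, criteria,
                control_label=self.control_label, equal_var=self.equal_var,
            )
        self.union_genes_ = de.union_signatures(list(self.signatures_.values()))
        self.feature_names_in_ = np.asarray(expr.index)
        self.support_ = np.array([g in self.union_genes_ for g in expr.index])
        self.n_features_in_ = expr.shape[0]
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of genes than at fit time")
        return X[:, self.support_]


class WGCNA(BaseEstimator, ClusterMixin):
    """Weighted gene co-expression network analysis of the input genes.

    ``fit`` expects ``X`` of shape (n_samples, n_genes); the clustering
    is over the genes (columns).  The pipeline is: Pearson correlation,
    unsigned power adjacency at the soft threshold ``beta`` (chosen by
    the smallest-power scale-free rule when "auto"), topological
    overlap, average-linkage dendrogram on 1 - TOM, dynamic tree cut,
    colour naming by falling module size, and intramodular connectivity.

    Attributes
    ----------
    beta_ : the soft-threshold power used
    scale_free_fits_ : dict beta -> ScaleFreeFit (when beta="auto")
    adjacency_, tom_ : gene x gene DataFrames
    linkage_ : scipy linkage matrix of the 1 - TOM dendrogram
    labels_ : per-gene module colour array ("grey" when unassigned)
    assignment_ : the ModuleAssignment
    hub_table_ : per-gene k.in table with hub selection flags
    """

    def __init__(
        self,
        beta: int | str = "auto",
        beta_grid: tuple = tuple(range(1, 21)),
        r2_threshold: float = 0.75,
        n_bins: int = 10,
        min_module_size: int = 20,
        deep_split: int = 2,
        cut_height_fraction: float = 0.99,
        hub_fraction: float = 0.10,
        hub_fraction_overrides: dict | None = None,
    ):
        self.beta = beta
        self.beta_grid = beta_grid
        self.r2_threshold = r2_threshold
        self.n_bins = n_bins
        self.min_module_size = min_module_size
        self.deep_split = deep_split
        self.cut_height_fraction = cut_height_fraction
        self.hub_fraction = hub_fraction
        self.hub_fraction_overrides = hub_fraction_overrides

    def fit(self, X, y=None):
        expr = _to_expr_frame(X)
        genes = list(expr.index)
        cor = network.correlation_matrix(expr)
        self.scale_free_fits_ = {}
        self.beta_warning_ = False
        if self.beta == "auto":
            beta, fits, warned = network.pick_beta(
                cor, beta_grid=list(self.beta_grid),
                r2_threshold=self.r2_threshold, n_bins=self.n_bins,
                is_correlation=True,
            )
            self.scale_free_fits_ = fits
            self.beta_warning_ = warned
        else:
            beta = int(self.beta)
        self.beta_ = beta
        self.correlation_ = cor
        self.adjacency_ = network.adjacency(cor, beta)
        self.connectivity_ = network.connectivity(self.adjacency_)
        self.tom_ = network.tom(self.adjacency_)
        d = dissimilarity(self.tom_)
        self.linkage_ = average_linkage(d)
        raw = dynamic_tree_cut(
            self.linkage_, d, min_size=self.min_module_size,
            deep_split=self.deep_split, cut_height_fraction=self.cut_height_fraction,
        )
        self.assignment_ = assign_colors(
            raw, genes, min_size=self.min_module_size,
            parameters={"deep_split": self.deep_split,
                        "cut_height_fraction": self.cut_height_fraction,
                        "beta": beta},
        )
        self.labels_ = self.assignment_.labels(genes)
        table = hubs.intramodular_connectivity(self.adjacency_, self.assignment_)
        self.hub_table_ = hubs.select_hubs(
            table, fraction_default=self.hub_fraction,
            fraction_overrides=self.hub_fraction_overrides,
        )
        self.feature_names_in_ = np.asarray(genes)
        self.n_features_in_ = len(genes)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    @property
    def module_sizes_(self) -> dict[str, int]:
        check_is_fitted(self, "assignment_")
        return dict(self.assignment_.module_sizes)

    @property
    def grey_count_(self) -> int:
        check_is_fitted(self, "assignment_")
        return self.assignment_.grey_count
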