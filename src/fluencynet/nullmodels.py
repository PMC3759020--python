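"""Random-graph null models and bootstrap comparison of word networks.

Two validation devices:

* an Erdos-Renyi G(n, p) ensemble matched to a network in node count and
  edge probability, giving reference distributions of L, D and CC and
  add-one empirical p-values for the observed statistics;
* a node-subsampling bootstrap that repeatedly draws a word subset, rebuilds
  each group's partial network from its correlation submatrix, and compares
  the resulting metric distributions between groups with a pooled
  independent t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .correlation import CorrelationMatrix
from .netmetrics import _distances, _local_clustering, aspl, clustering, diameter

logger = logging.getLogger(__name__)

__all__ = [
    "ERSpec",
    "MetricDistribution",
    "ERNullResult",
    "BootstrapComparison",
    "TTestResult",
    "simulate_er",
    "empirical_significance",
    "bootstrap_partial",
    "two_sample_t",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ValueError):
    """Raised when a test statistic is undefined (e.g. zero pooled variance)."""


@dataclass(frozen=True)
class ERSpec:
    """Specification of an Erdos-Renyi G(n, p) ensemble."""

    n: int
    p: float
    realizations: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"need at least 3 nodes, got {self.n}")
        if not 0 < self.p <= 1:
            raise ValueError(f"edge probability must be in (0, 1], got {self.p}")
        if self.realizations < 1:
            raise ValueError("need at least 1 realization")

    @classmethod
    def matched(
        cls, n: int, n_edges: int, realizations: int = 10_000, seed: int | None = None
    ) -> "ERSpec":
        """Ensemble matched to an observed network: p = E / (N(N-1)/2)."""
        return cls(n=n, p=n_edges / (n * (n - 1) / 2.0), realizations=realizations, seed=seed)


@dataclass
class MetricDistribution:
    """Simulated distribution of one network metric."""

    name: str
    values: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mean = float(self.values.mean())
        self.sd = float(self.values.std(ddof=1)) if self.values.size > 1 else 0.0

    @property
    def realizations(self) -> int:
        return int(self.values.size)

    def summary(self, digits: int = 2) -> str:
        return f"{self.mean:.{digits}f} ({self.sd:.{digits}f})"


@dataclass
class ERNullResult:
    """Reference distributions from a matched G(n, p) ensemble.

    ``l`` is the average shortest path length over distinct node pairs;
    ``l_char`` is the characteristic-path-length variant that averages the
    distance matrix including its zero diagonal (the convention of some
    toolboxes; it equals l * (m-1)/m on an m-node component).  ``d`` is the
    diameter and ``cc`` the mean local clustering.  L and D follow the
    configured disconnection policy; CC is always computed on the full
    graph.  ``disconnected_fraction`` reports how often a draw was
    disconnected (at the densities of interest here this is a noticeable
    minority of draws, driven mostly by isolated nodes).
    """

    spec: ERSpec
    l: MetricDistribution
    d: MetricDistribution
    cc: MetricDistribution
    l_char: MetricDistribution
    disconnected_fraction: float
    policy: str

    def table_row(self) -> dict:
        return {
            "L": self.l.summary(),
            "D": self.d.summary(),
            "CC": self.cc.summary(),
        }


def simulate_er(spec: ERSpec, disconnection_policy: str = "largest_component") -> ERNullResult:
    """Simulate a matched Erdos-Renyi ensemble and collect L, D, CC.

    ``disconnection_policy`` controls path metrics on disconnected draws:
    ``"largest_component"`` (default) computes L and D on the largest
    connected component and logs the occurrence; ``"resample"`` redraws
    until connected.  Clustering is always computed on the full graph, with
    degree-<2 nodes contributing 0.
    """
    if disconnection_policy not in ("largest_component", "resample"):
        raise ValueError(f"unknown disconnection policy {disconnection_policy!r}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    iu = np.triu_indices(n, 1)
    n_pairs = iu[0].size
    ls = np.empty(spec.realizations)
    ls_char = np.empty(spec.realizations)
    ds = np.empty(spec.realizations)
    ccs = np.empty(spec.realizations)
    n_disconnected = 0
    for r in range(spec.realizations):
        while True:
            adj = np.zeros((n, n), dtype=np.int8)
            mask = rng.random(n_pairs) < spec.p
            adj[iu[0][mask], iu[1][mask]] = 1
            adj |= adj.T
            n_comp, labels = connected_components(sparse.csr_matrix(adj), directed=False)
            if n_comp == 1:
                break
            n_disconnected += 1
            if disconnection_policy == "largest_component":
                sizes = np.bincount(labels)
                keep = labels == sizes.argmax()
                break
        ccs[r] = _local_clustering(adj).mean()
        sub = adj if n_comp == 1 else adj[np.ix_(keep, keep)]
        m = sub.shape[0]
        if m < 2:
            ls[r] = ls_char[r] = 0.0
            ds[r] = 0.0
            continue
        dist = _distances(sub)
        offdiag_sum = dist.sum()  # diagonal is zero
        ls[r] = offdiag_sum / (m * (m - 1))
        ls_char[r] = offdiag_sum / (m * m)
        ds[r] = dist.max()
    frac = n_disconnected / (spec.realizations + (n_disconnected if disconnection_policy == "resample" else 0))
    if n_disconnected:
        logger.info(
            "%d/%d G(%d, %.4f) draws disconnected (policy=%s)",
            n_disconnected, spec.realizations, n, spec.p, disconnection_policy,
        )
    return ERNullResult(
        spec=spec,
        l=MetricDistribution("L", ls),
        d=MetricDistribution("D", ds),
        cc=MetricDistribution("CC", ccs),
        l_char=MetricDistribution("L_char", ls_char),
        disconnected_fraction=frac,
        policy=disconnection_policy,
    )


def empirical_significance(
    observed: float, dist: MetricDistribution, side: str = "two"
) -> float:
    """Add-one empirical p-value of an observed value against a simulated null.

    p = (1 + #{simulated at least as extreme}) / (realizations + 1); the
    add-one smoothing keeps p > 0.  ``side="two"`` doubles the smaller
    one-sided p (capped at 1).
    """
    values = dist.values
    r = values.size
    p_greater = (1 + int((values >= observed).sum())) / (r + 1)
    p_less = (1 + int((values <= observed).sum())) / (r + 1)
    if side == "greater":
        return p_greater
    if side == "less":
        return p_less
    if side == "two":
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise ValueError(f"unknown side {side!r}")


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def two_sample_t(x, y) -> TTestResult:
    """Pooled-variance independent two-sample t-test; df = n_x + n_y - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
        x.size + y.size - 2
    )
    if pooled == 0:
        raise UndefinedStatisticError("zero pooled variance: t is undefined")
    res = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(res.statistic), df=x.size + y.size - 2, p=float(res.pvalue))


@dataclass
class BootstrapComparison:
    """Partial-network bootstrap comparison of two groups.

    Per realization a word subset of size ``subset_size`` is drawn, each
    group's partial network is REBUILT from its correlation submatrix (not
    cut out of the full network), and L, D, CC are recorded.  The per-metric
    group comparison is a pooled t-test over the two realization vectors;
    treating bootstrap realizations as independent observations mirrors the
    published analysis but is anticonservative, so the p-values should be
    read as descriptive.
    """

    group_labels: tuple[str, str]
    subset_size: int
    realizations: int
    shared_subsets: bool
    distributions: dict  # {group_label: {metric: MetricDistribution}}
    tests: dict  # {metric: TTestResult}

    def summary_table(self) -> dict:
        out: dict = {}
        for metric in ("L", "D", "CC"):
            digits = 3 if metric == "CC" else 2
            row = {
                g: self.distributions[g][metric].summary(digits)
                for g in self.group_labels
            }
            row["t"] = round(self.tests[metric].t, 3)
            row["df"] = self.tests[metric].df
            row["p"] = self.tests[metric].p
            out[metric] = row
        return out


def bootstrap_partial(
    c_a: CorrelationMatrix,
    c_b: CorrelationMatrix,
    subset_size: int = 40,
    realizations: int = 10_000,
    seed: int | None = None,
    shared_subsets: bool = True,
    group_labels: tuple[str, str] = ("a", "b"),
) -> BootstrapComparison:
    """Bootstrapped partial-network comparison of two word-matched groups.

    Both correlation matrices must share the same vocabulary.  With
    ``shared_subsets=True`` (default) the same word subset is used for both
    groups within a realization, which removes subset-choice noise from the
    between-group contrast; independent subsets are available for the
    stricter reading of the procedure.
    """
    from .pmfg import build_pmfg  # deferred: avoids import cycle

    if sorted(c_a.vocabulary) != sorted(c_b.vocabulary):
        raise ValueError("both groups must share the same (word-matched) vocabulary")
    vocab = sorted(c_a.vocabulary)
    if not 3 <= subset_size <= len(vocab):
        raise ValueError(
            f"subset_size must be in [3, {len(vocab)}], got {subset_size}"
        )
    rng = np.random.default_rng(seed)
    values: dict[str, dict[str, np.ndarray]] = {
        g: {m: np.empty(realizations) for m in ("L", "D", "CC")} for g in group_labels
    }
    mats = dict(zip(group_labels, (c_a, c_b)))
    for r in range(realizations):
        subset_a = sorted(rng.choice(vocab, size=subset_size, replace=False))
        subset_b = subset_a if shared_subsets else sorted(
            rng.choice(vocab, size=subset_size, replace=False)
        )
        for g, subset in zip(group_labels, (subset_a, subset_b)):
            net = build_pmfg(mats[g].restrict(subset), network_kind="partial", group_label=g)
            values[g]["L"][r] = aspl(net)
            values[g]["D"][r] = diameter(net)
            values[g]["CC"][r] = clustering(net)
    distributions = {
        g: {m: MetricDistribution(m, v) for m, v in per.items()}
        for g, per in values.items()
    }
    tests = {}
    for metric in ("L", "D", "CC"):
        ga, gb = group_labels
        try:
            tests[metric] = two_sample_t(values[ga][metric], values[gb][metric])
        except UndefinedStatisticError:
            tests[metric] = TTestResult(t=0.0, df=2 * realizations - 2, p=1.0)
    return BootstrapComparison(
        group_labels=group_labels,
        subset_size=subset_size,
        realizations=realizations,
        shared_subsets=shared_subsets,
        distributions=distributions,
        tests=tests,
    )
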