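"""Pseudo-haploid diversity statistics and their PLS reduction.

The pairwise pseudo-haploid nucleotide diversity of two genomes is the
number of mismatching sites divided by the number of sites compared, pooled
over all loci.  Genomes are grouped into "population samples" (same deme,
same population layer, mean ages within 300 years, with the maximum
intragroup age span kept below the minimum intergroup age gap); the summary
statistic vector then lists the mean diversity within each sample of size
>= 2 followed by the mean diversity between every unordered pair of samples,
both blocks in canonical (label-sorted) order.  For the study's 23-sample
scheme this yields 14 + C(23,2) = 267 values.

For ABC parameter estimation the statistic vector is reduced to a small
number of partial-least-squares components after a per-statistic Box-Cox
power transform; the component count is chosen where adding one more
improves the training RMSE of every parameter by less than a threshold
(default 2%).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.preprocessing import PowerTransformer, StandardScaler
from sklearn.utils.validation import check_is_fitted

from .coalescent import SequencePanel


def pairwise_diversity(panel: SequencePanel) -> np.ndarray:
    """Symmetric matrix of pairwise mismatch fractions pooled over loci."""
    X = panel.stacked()  # (n, total_sites)
    n, sites = X.shape
    div = np.zeros((n, n))
    for i in range(n):
        mism = (X[i + 1 :] != X[i]).sum(axis=1)
        div[i, i + 1 :] = mism / sites
    div += div.T
    np.fill_diagonal(div, np.nan)  # within-genome diversity undefined
    return div


def n_pairwise_values(n_genomes: int) -> int:
    """Number of unordered genome pairs, e.g. 67 genomes -> 2211."""
    return n_genomes * (n_genomes - 1) // 2


@dataclass
class SampleGrouping:
    """Assignment of genomes to population samples.

    ``assignment`` maps genome index -> sample label; ``samples`` lists per
    sample (label-sorted) its member genome indices and metadata.
    """

    assignment: list[str]
    samples: pd.DataFrame  # index: label; columns deme, layer, mean_age, n
    members: dict[str, list[int]]

    @property
    def labels(self) -> list[str]:
        return sorted(self.members)

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.members.items()}


def group_genomes(
    metadata: pd.DataFrame,
    max_age_diff: float = 300.0,
) -> SampleGrouping:
    """Group genomes into population samples by deme, layer and age.

    Within each (deme, layer): genomes are age-sorted and split wherever
    adjacent ages differ by more than ``max_age_diff`` years; any cluster
    whose age span (diameter) still exceeds ``max_age_diff`` is split at its
    largest internal age gap, and clusters whose span reaches the smallest
    gap to a neighbouring cluster are split the same way.  A genome within
    reach of two groups therefore ends up on the side that keeps every
    intragroup span below the intergroup difference.
    """
    required = {"deme", "layer", "age"}
    if not required <= set(metadata.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    assignment = [""] * len(metadata)
    members: dict[str, list[int]] = {}
    rows = []
    for (deme, layer), sub in metadata.groupby(["deme", "layer"], sort=True):
        idx = sub.index.to_numpy()
        ages = sub["age"].to_numpy(dtype=float)
        order = np.argsort(ages, kind="stable")
        idx, ages = idx[order], ages[order]
        # initial split on the 300-year adjacency rule
        breaks = list(np.nonzero(np.diff(ages) > max_age_diff)[0] + 1)
        clusters = np.split(np.arange(len(ages)), breaks)
        # the age diameter of a group may not exceed the 300-year limit
        stack = list(clusters)
        clusters = []
        while stack:
            cl = stack.pop(0)
            if len(cl) > 1 and ages[cl[-1]] - ages[cl[0]] > max_age_diff:
                cut = int(np.argmax(np.diff(ages[cl]))) + 1
                stack = [cl[:cut], cl[cut:]] + stack
            else:
                clusters.append(cl)
        clusters.sort(key=lambda cl: ages[cl[0]])
        # enforce intragroup span < intergroup gap by splitting offenders
        changed = True
        while changed and len(clusters) >= 1:
            changed = False
            gaps = [
                ages[clusters[j + 1][0]] - ages[clusters[j][-1]]
                for j in range(len(clusters) - 1)
            ]
            if not gaps:
                break
            min_gap = min(gaps)
            for j, cl in enumerate(clusters):
                span = ages[cl[-1]] - ages[cl[0]]
                if len(cl) > 1 and span >= min_gap:
                    internal = np.diff(ages[cl])
                    cut = int(np.argmax(internal)) + 1
                    clusters = (
                        clusters[:j] + [cl[:cut], cl[cut:]] + clusters[j + 1 :]
                    )
                    changed = True
                    break
        for k, cl in enumerate(clusters):
            label = f"{deme}.{layer}.{k + 1}"
            members[label] = [int(i) for i in idx[cl]]
            for i in idx[cl]:
                assignment[int(i)] = label
            rows.append(
                {
                    "label": label,
                    "deme": deme,
                    "layer": layer,
                    "mean_age": float(ages[cl].mean()),
                    "n": len(cl),
                }
            )
    samples = pd.DataFrame(rows).set_index("label").sort_index()
    return SampleGrouping(assignment=assignment, samples=samples, members=members)


def grouping_from_scheme(scheme) -> SampleGrouping:
    """The trivial grouping in which each scheme sample is one group."""
    members: dict[str, list[int]] = {}
    assignment = []
    rows = []
    i = 0
    for s in scheme.samples:
        members[s.label] = list(range(i, i + s.n_individuals))
        assignment += [s.label] * s.n_individuals
        rows.append(
            {
                "label": s.label,
                "deme": (s.x, s.y),
                "layer": s.layer,
                "mean_age": s.mean_age,
                "n": s.n_individuals,
            }
        )
        i += s.n_individuals
    samples = pd.DataFrame(rows).set_index("label").sort_index()
    return SampleGrouping(assignment=assignment, samples=samples, members=members)


def expected_length(grouping: SampleGrouping) -> int:
    """Length of the statistic vector: |{samples n>=2}| + C(S, 2)."""
    sizes = grouping.sizes()
    s = len(sizes)
    return sum(1 for n in sizes.values() if n >= 2) + s * (s - 1) // 2


def stat_names(grouping: SampleGrouping) -> list[str]:
    labels = grouping.labels
    sizes = grouping.sizes()
    names = [f"within:{l}" for l in labels if sizes[l] >= 2]
    names += [f"between:{a}|{b}" for a, b in combinations(labels, 2)]
    return names


def stat_vector(div: np.ndarray, grouping: SampleGrouping) -> np.ndarray:
    """Within-sample then between-sample mean diversities, canonical order."""
    labels = grouping.labels
    sizes = grouping.sizes()
    out = []
    for l in labels:
        if sizes[l] >= 2:
            m = grouping.members[l]
            sub = div[np.ix_(m, m)]
            iu = np.triu_indices(len(m), k=1)
            out.append(float(sub[iu].mean()))
    for a, b in combinations(labels, 2):
        out.append(float(div[np.ix_(grouping.members[a], grouping.members[b])].mean()))
    return np.array(out)


def panel_stat_vector(panel: SequencePanel, grouping: SampleGrouping) -> np.ndarray:
    return stat_vector(pairwise_diversity(panel), grouping)


class PLSReducer(TransformerMixin, BaseEstimator):
    """Box-Cox power transform + partial-least-squares reduction of stats.

    Fit on a matrix of simulated statistic vectors X and the matching
    parameter draws Y; ``transform`` maps any statistic vector (simulated or
    observed) to ``n_components_`` PLS scores.  With
    ``n_components='auto'`` the smallest component count is kept for which
    adding one more component improves the training RMSE of every parameter
    by less than ``rmse_threshold`` (relative), capped at ``max_components``.
    """

    def __init__(
        self,
        n_components: int | str = "auto",
        max_components: int = 10,
        rmse_threshold: float = 0.02,
        power_transform: bool = True,
    ):
        self.n_components = n_components
        self.max_components = max_components
        self.rmse_threshold = rmse_threshold
        self.power_transform = power_transform

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSReducer":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if X.shape[0] < 20:
            raise ValueError("need at least 20 rows to fit the reduction")
        keep = np.ptp(X, axis=0) > 0
        if not keep.any():
            raise ValueError("all statistic columns are constant")
        self.kept_columns_ = np.nonzero(keep)[0]
        Xk = X[:, keep]
        self.shift_ = Xk.min(axis=0)
        method = "box-cox" if self.power_transform else None
        if method:
            self.power_ = PowerTransformer(method=method, standardize=True)
        else:
            self.power_ = StandardScaler()
        Xt = self.power_.fit_transform(Xk - self.shift_ + 1.0)
        # keep >= 10x more rows than fitted components
        kmax = int(min(self.max_components, Xt.shape[1], X.shape[0] // 10))
        kmax = max(kmax, 1)
        self.rmse_curve_ = np.empty((kmax, y.shape[1]))
        for k in range(1, kmax + 1):
            pls = PLSRegression(n_components=k, scale=True).fit(Xt, y)
            resid = y - pls.predict(Xt)
            self.rmse_curve_[k - 1] = np.sqrt((resid**2).mean(axis=0))
        if self.n_components == "auto":
            self.n_components_ = choose_components(
                self.rmse_curve_, self.rmse_threshold
            )
        else:
            self.n_components_ = int(self.n_components)
        self.pls_ = PLSRegression(n_components=self.n_components_, scale=True).fit(
            Xt, y
        )
        self.training_scores_ = self._scores(Xt)
        return self

    def _scores(self, Xt: np.ndarray) -> np.ndarray:
        return self.pls_.transform(Xt)

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "pls_")
        X = np.asarray(X, dtype=float)
        one = X.ndim == 1
        if one:
            X = X[None, :]
        Xk = X[:, self.kept_columns_]
        # Box-Cox needs positive inputs; clip below the training support
        Xt = self.power_.transform(np.maximum(Xk - self.shift_ + 1.0, 1e-12))
        scores = self._scores(Xt)
        return scores[0] if one else scores


def save_pls(reducer: PLSReducer, path) -> None:
    """Serialize a fitted reducer to a single portable file (joblib)."""
    import joblib

    check_is_fitted(reducer, "pls_")
    joblib.dump(reducer, path)


def load_pls(path) -> PLSReducer:
    import joblib

    reducer = joblib.load(path)
    check_is_fitted(reducer, "pls_")
    return reducer


def choose_components(rmse_curve: np.ndarray, threshold: float = 0.02) -> int:
    """Smallest k whose k->k+1 relative RMSE gain is < threshold for all params."""
    rmse_curve = np.atleast_2d(np.asarray(rmse_curve, dtype=float))
    kmax = rmse_curve.shape[0]
    for k in range(1, kmax):
        prev, nxt = rmse_curve[k - 1], rmse_curve[k]
        improvement = (prev - nxt) / np.where(prev > 0, prev, 1.0)
        if np.all(improvement < threshold):
            return k
    return kmax


def fit_pls(
    sim_stats: np.ndarray,
    sim_params: np.ndarray,
    max_components: int = 10,
    rmse_threshold: float = 0.02,
) -> PLSReducer:
    return PLSReducer(
        max_components=max_components, rmse_threshold=rmse_threshold
    ).fit(sim_stats, sim_params)


def apply_pls(reducer: PLSReducer, v: np.ndarray) -> np.ndarray:
    return reducer.transform(v)


def write_stat_table(
    path, vectors: np.ndarray, names: Sequence[str], index=None
) -> None:
    """TSV serialization of one or many statistic vectors."""
    df = pd.DataFrame(np.atleast_2d(vectors), columns=list(names), index=index)
    df.to_csv(path, sep="\t", index=index is not None)
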