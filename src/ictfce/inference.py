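"""Max-statistic permutation inference over any TFCE engine.

Familywise error is controlled by comparing each edge's observed TFCE value
against the permutation distribution of the GLOBAL maximum TFCE: an edge is
significant only if its enhancement exceeds what the strongest edge anywhere
in the matrix reaches under exchangeability.  p-values use the
``(1 + exceedances) / (n_perm + 1)`` estimator, so they are never zero and
the test is exact-level.

Every permutation's TFCE rebuilds its threshold grid from that permuted
map's own maximum statistic, following the definition ``nth = tmax/dh``;
nth therefore varies across permutations.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .core import StatMatrix, TFCEMap, TFCEParams, ValidationError
from .exact import tfce_exact_edges
from .incremental import DEFAULT_MAX_ACCUMULATOR_ENTRIES, _ic_tfce_edges
from .reference import tfce_discrete

logger = logging.getLogger(__name__)

__all__ = [
    "GroupDataset",
    "NullDistribution",
    "PermutationResult",
    "PowerResult",
    "group_tstats",
    "permutation_test",
    "estimate_power",
]

Engine = Literal["reference", "incremental", "exact"]
Tails = Literal["pos", "neg", "both"]


@dataclass(frozen=True)
class GroupDataset:
    """Per-subject symmetric FC matrices plus a group design.

    ``groups`` holds 0/1 labels for a two-sample design, or ``None`` for a
    one-sample (test against zero) design.
    """

    subjects: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        subs = np.asarray(self.subjects, dtype=float)
        if subs.ndim != 3 or subs.shape[1] != subs.shape[2]:
            raise ValidationError(
                f"subjects must be n_sub x N x N, got shape {subs.shape}"
            )
        if subs.shape[0] < 4:
            raise ValidationError(f"need at least 4 subjects, got {subs.shape[0]}")
        if not np.isfinite(subs).all():
            raise ValidationError("non-finite value in subject data")
        if np.abs(subs - subs.transpose(0, 2, 1)).max() > 1e-9:
            raise ValidationError("subject matrices must be symmetric")
        object.__setattr__(self, "subjects", subs)
        if self.groups is not None:
            g = np.asarray(self.groups)
            if g.shape != (subs.shape[0],):
                raise ValidationError("one group label per subject required")
            if not set(np.unique(g)) <= {0, 1}:
                raise ValidationError("group labels must be 0/1")
            if (g == 0).sum() < 2 or (g == 1).sum() < 2:
                raise ValidationError("each group needs at least 2 subjects")
            object.__setattr__(self, "groups", g.astype(np.int64))

    @property
    def n_sub(self) -> int:
        return self.subjects.shape[0]

    @property
    def n_rois(self) -> int:
        return self.subjects.shape[1]

    def edge_data(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(iu, iv, X) with X of shape (n_sub, n_edges)."""
        iu, iv = np.triu_indices(self.n_rois, k=1)
        return iu, iv, self.subjects[:, iu, iv]


@dataclass(frozen=True)
class NullDistribution:
    """Per-permutation global maxima of the TFCE map."""

    max_tfce: np.ndarray
    n_perm: int
    seed: int


@dataclass(frozen=True)
class PermutationResult:
    """FWER-corrected edgewise p-values plus the pieces behind them."""

    p_values: np.ndarray
    observed_tfce: TFCEMap
    null: NullDistribution
    params: TFCEParams
    engine: str
    tails: str


@dataclass(frozen=True)
class PowerResult:
    """Edgewise rejection frequencies over repeated simulated datasets."""

    rejection_freq: np.ndarray
    overall_average_power: float
    per_network: dict[str, float] | None
    alpha: float
    n_reps: int

    def top_networks(self) -> list[tuple[str, float]]:
        """Networks ranked by mean power, descending."""
        if self.per_network is None:
            return []
        return sorted(self.per_network.items(), key=lambda kv: -kv[1])


def _tstats_vec(x: np.ndarray, groups: np.ndarray | None) -> np.ndarray:
    """Edgewise t statistics on (n_sub, n_edges) data; zero-variance -> 0."""
    n_sub = x.shape[0]
    if groups is None:
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / math.sqrt(n_sub))
    else:
        x0 = x[groups == 0]
        x1 = x[groups == 1]
        n0, n1 = x0.shape[0], x1.shape[0]
        v0 = x0.var(axis=0, ddof=1)
        v1 = x1.var(axis=0, ddof=1)
        sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (x1.mean(axis=0) - x0.mean(axis=0)) / np.sqrt(sp2 * (1 / n0 + 1 / n1))
    bad = ~np.isfinite(t)
    if bad.any():
        logger.warning(
            "zero variance at %d edge(s); their t statistics were set to 0",
            int(bad.sum()),
        )
        t = np.where(bad, 0.0, t)
    return t


def group_tstats(d: GroupDataset) -> StatMatrix:
    """Edgewise t-statistic matrix: pooled two-sample (group B minus group A)
    or one-sample against zero, per the dataset's design."""
    iu, iv, x = d.edge_data()
    t = _tstats_vec(x, d.groups)
    values = np.zeros((d.n_rois, d.n_rois))
    values[iu, iv] = t
    values[iv, iu] = t
    return StatMatrix(values=values)


def _engine_edge_tfce(
    n: int,
    iu: np.ndarray,
    iv: np.ndarray,
    stats: np.ndarray,
    p: TFCEParams,
    engine: str,
) -> np.ndarray:
    if engine == "incremental":
        vals, _, _ = _ic_tfce_edges(n, iu, iv, stats, p, DEFAULT_MAX_ACCUMULATOR_ENTRIES)
        return vals
    if engine == "exact":
        return tfce_exact_edges(n, iu, iv, stats, p.E, p.H)
    if engine == "reference":
        values = np.zeros((n, n))
        values[iu, iv] = stats
        values[iv, iu] = stats
        return tfce_discrete(StatMatrix(values), p).values[iu, iv]
    raise ValidationError(f"unknown engine {engine!r}")


def _n_distinct_relabelings(groups: np.ndarray | None, n_sub: int) -> float:
    if groups is None:
        return 2.0**n_sub
    n1 = int((groups == 1).sum())
    return float(math.comb(n_sub, n1))


def _one_tail_pvalues(
    obs: np.ndarray,
    n: int,
    iu: np.ndarray,
    iv: np.ndarray,
    x: np.ndarray,
    groups: np.ndarray | None,
    p: TFCEParams,
    engine: str,
    perms: list,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(p per edge, observed tfce per edge, null maxima) for one tail."""
    obs_tfce = _engine_edge_tfce(n, iu, iv, obs, p, engine)
    maxima = np.empty(len(perms))
    for i, perm in enumerate(perms):
        if groups is None:
            t = _tstats_vec(perm[:, None] * x, None)
        else:
            t = _tstats_vec(x, perm)
        vals = _engine_edge_tfce(n, iu, iv, t, p, engine)
        maxima[i] = vals.max() if vals.size else 0.0
    sorted_max = np.sort(maxima)
    exceed = len(perms) - np.searchsorted(sorted_max, obs_tfce, side="left")
    pvals = (1.0 + exceed) / (len(perms) + 1.0)
    return pvals, obs_tfce, maxima


def permutation_test(
    d: GroupDataset,
    p: TFCEParams,
    engine: Engine = "incremental",
    n_perm: int = 1000,
    seed: int = 0,
    tails: Tails = "pos",
) -> PermutationResult:
    """Max-TFCE permutation test with FWER-corrected edgewise p-values.

    Two-sample designs shuffle group labels; one-sample designs flip subject
    signs.  ``tails='both'`` runs the positive and negative tails separately
    and Bonferroni-doubles the smaller p-value.  The same seed yields the
    identical permutation sequence for every engine, so engine choice cannot
    change the inference beyond TFCE numerics.
    """
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    iu, iv, x = d.edge_data()
    n = d.n_rois
    if n_perm > _n_distinct_relabelings(d.groups, d.n_sub):
        warnings.warn(
            f"n_perm={n_perm} exceeds the number of distinct relabelings; "
            "permutations are sampled with replacement",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    if d.groups is None:
        perms = [rng.choice([-1.0, 1.0], size=d.n_sub) for _ in range(n_perm)]
    else:
        perms = [rng.permutation(d.groups) for _ in range(n_perm)]
    t_obs = _tstats_vec(x, d.groups)
    p_pos, tfce_pos, maxima = _one_tail_pvalues(
        t_obs, n, iu, iv, x, d.groups, p, engine, perms
    )
    if tails == "pos":
        pvals, tfce_edge = p_pos, tfce_pos
    elif tails == "neg":
        pvals, tfce_edge, maxima = _one_tail_pvalues(
            -t_obs, n, iu, iv, -x, d.groups, p, engine, perms
        )
    elif tails == "both":
        p_neg, tfce_neg, _ = _one_tail_pvalues(
            -t_obs, n, iu, iv, -x, d.groups, p, engine, perms
        )
        pvals = np.minimum(1.0, 2.0 * np.minimum(p_pos, p_neg))
        tfce_edge = np.maximum(tfce_pos, tfce_neg)
    else:
        raise ValidationError(f"tails must be pos, neg or both; got {tails!r}")
    p_matrix = np.ones((n, n))
    p_matrix[iu, iv] = pvals
    p_matrix[iv, iu] = pvals
    return PermutationResult(
        p_values=p_matrix,
        observed_tfce=TFCEMap.from_edge_values(n, iu, iv, tfce_edge),
        null=NullDistribution(max_tfce=maxima, n_perm=n_perm, seed=seed),
        params=p,
        engine=engine,
        tails=tails,
    )


def estimate_power(
    config,
    params: TFCEParams | Sequence[TFCEParams],
    n_reps: int = 100,
    alpha: float = 0.05,
    n_perm: int = 100,
    engine: Engine = "incremental",
    seed: int = 0,
    networks: np.ndarray | None = None,
    tails: Tails = "pos",
):
    """Empirical power over repeated generated datasets with a planted effect.

    ``config`` is a :class:`ictfce.synth.SynthGroupConfig`.  When a sequence
    of ``params`` is given (e.g. to compare dh values), every parameter set
    within a repetition sees the identical subject draw and permutation
    sequence, so power differences reflect the parameters alone; a dict
    keyed by the parameter sets is returned.  ``networks`` is an optional
    per-node labeling; per-network power averages the rejection frequency
    over edges with both endpoints inside the network.
    """
    from .synth import synth_group_dataset  # local import avoids a module cycle

    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    single = isinstance(params, TFCEParams)
    params_list = [params] if single else list(params)
    master = np.random.default_rng(seed)
    data_seeds = master.integers(0, 2**31 - 1, size=n_reps)
    perm_seeds = master.integers(0, 2**31 - 1, size=n_reps)
    n = config.n_rois
    counts = {prm: np.zeros((n, n)) for prm in params_list}
    for r in range(n_reps):
        d = synth_group_dataset(replace(config, seed=int(data_seeds[r])))
        for prm in params_list:
            res = permutation_test(
                d, prm, engine=engine, n_perm=n_perm, seed=int(perm_seeds[r]), tails=tails
            )
            counts[prm] += res.p_values <= alpha
    iu, iv = np.triu_indices(n, k=1)
    results = {}
    for prm in params_list:
        freq = counts[prm] / n_reps
        np.fill_diagonal(freq, 0.0)
        per_network = None
        if networks is not None:
            labels = np.asarray([str(x) for x in networks])
            per_network = {}
            for name in sorted(set(labels)):
                sel = (labels[iu] == name) & (labels[iv] == name)
                if sel.any():
                    per_network[name] = float(freq[iu[sel], iv[sel]].mean())
        results[prm] = PowerResult(
            rejection_freq=freq,
            overall_average_power=float(freq[iu, iv].mean()),
            per_network=per_network,
            alpha=alpha,
            n_reps=n_reps,
        )
    return results[params_list[0]] if single else results
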