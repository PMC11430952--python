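"""Pairwise p-distances and partitioned maximum-likelihood distances.

The ML distance between two aligned sequences is the branch length t
maximizing the two-sequence likelihood

    l(t) = sum_partitions sum_{x,y} n_xy * log sum_c (1/C) pi_x P_xy(t r_c)

with one shared t across partitions, each partition carrying its own
fully parameterized :class:`~gyrits.models.SubstitutionModel`.  Sites
with a gap or ambiguity in either row are excluded per partition
(pairwise deletion); the same policy applies to p-distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .models import (BASES, BASE_INDEX, EXCH_KEYS, SubstitutionModel,
                     build_rate_matrix, transition_probabilities)

T_MIN = 1e-6
T_MAX = 10.0
_OPT_TOL = 1e-8

_VALID = frozenset(BASES)


@dataclass(frozen=True)
class Partition:
    """A named, 1-based inclusive column range bound to a model."""
    name: str
    start: int
    end: int
    model: SubstitutionModel

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad partition range {self.start}-{self.end}")

    @property
    def sl(self) -> slice:
        return slice(self.start - 1, self.end)


@dataclass
class PartitionedAlignment:
    """Aligned rows plus non-overlapping named column ranges."""
    ids: list
    rows: list          # uppercase strings, equal length
    partitions: list    # list[Partition]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        width = len(self.rows[0]) if self.rows else 0
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows differ in length")
        covered = []
        for p in self.partitions:
            if p.end > width:
                raise ValueError(f"partition {p.name} exceeds alignment width {width}")
            covered.append((p.start, p.end, p.name))
        covered.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(covered, covered[1:]):
            if s2 <= e1:
                raise ValueError(f"partitions {n1} and {n2} overlap")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id) -> str:
        return self.rows[self.ids.index(seq_id)]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with method metadata."""
    ids: list
    matrix: np.ndarray
    method: str                  # "p" or "ml"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(m < 0):
            raise ValueError("negative distances")
        self.matrix = m

    def get(self, a, b) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# p-distance


def p_distance(row_a: str, row_b: str, deletion: str = "pairwise",
               mask: np.ndarray | None = None):
    """Proportion of differing sites among comparable positions.

    Returns ``(distance, n_compared)``.  Under ``pairwise`` deletion a
    site is comparable when both rows carry an unambiguous base; under
    ``complete-set`` deletion the caller supplies ``mask``, the
    alignment-wide set of columns free of gaps/ambiguity in every row.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    if deletion not in ("pairwise", "complete-set"):
        raise ValueError(f"unknown deletion policy {deletion!r}")
    a = np.frombuffer(row_a.upper().encode(), dtype="S1")
    b = np.frombuffer(row_b.upper().encode(), dtype="S1")
    letters = [c.encode() for c in BASES]
    valid = np.isin(a, letters) & np.isin(b, letters)
    if deletion == "complete-set":
        if mask is None:
            raise ValueError("complete-set deletion requires a column mask")
        valid &= np.asarray(mask, dtype=bool)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable sites between the two rows")
    diff = int(np.sum((a != b) & valid))
    return diff / n, n


def complete_set_mask(rows) -> np.ndarray:
    """Columns with an unambiguous base in every row."""
    mats = [np.frombuffer(r.upper().encode(), dtype="S1") for r in rows]
    ok = np.ones(len(rows[0]), dtype=bool)
    letters = [c.encode() for c in BASES]
    for m in mats:
        ok &= np.isin(m, letters)
    return ok


# ---------------------------------------------------------------------------
# pairwise ML distance


def site_pattern_counts(row_a: str, row_b: str) -> np.ndarray:
    """4x4 table of comparable-site pattern counts (pairwise deletion)."""
    counts = np.zeros((4, 4))
    for x, y in zip(row_a.upper(), row_b.upper()):
        i = BASE_INDEX.get(x)
        j = BASE_INDEX.get(y)
        if i is not None and j is not None:
            counts[i, j] += 1
    return counts


def pair_loglik(counts_per_partition, t: float, models) -> float:
    """Partitioned two-sequence log-likelihood at branch length t."""
    total_sites = sum(float(np.sum(c)) for c in counts_per_partition)
    if total_sites == 0:
        raise ValueError("all-zero pattern counts")
    ll = 0.0
    for counts, model in zip(counts_per_partition, models):
        counts = np.asarray(counts, dtype=float)
        if counts.sum() == 0:
            continue
        P = transition_probabilities(model, t)       # (C,4,4)
        site_prob = model.pi[:, None] * P.mean(axis=0)
        with np.errstate(divide="ignore"):
            logp = np.log(site_prob)
        mask = counts > 0
        if np.any(np.isneginf(logp[mask])):
            return -np.inf
        ll += float(np.sum(counts[mask] * logp[mask]))
    return ll


def ml_distance(row_a: str, row_b: str, partitions):
    """Maximum-likelihood distance t-hat in expected substitutions/site.

    ``partitions`` is a list of :class:`Partition` covering (parts of)
    the rows; pattern counts are taken per partition with pairwise
    deletion.  Returns ``(t_hat, info)`` where ``info`` records the
    log-likelihood, compared sites and a saturation flag when the
    optimizer hits the upper bound.
    """
    counts = [site_pattern_counts(row_a[p.sl], row_b[p.sl]) for p in partitions]
    models = [p.model for p in partitions]
    if all(c.sum() == 0 for c in counts):
        raise ValueError("no comparable sites in any partition")
    neg = lambda t: -pair_loglik(counts, t, models)
    res = minimize_scalar(neg, bounds=(T_MIN, T_MAX), method="bounded",
                          options={"xatol": _OPT_TOL})
    t_hat = float(res.x)
    # the bounded optimizer never returns the exact bound; snap when flat
    if neg(T_MIN) <= res.fun + 1e-12:
        t_hat = T_MIN
    saturated = t_hat > T_MAX - 1e-3 and neg(T_MAX) <= res.fun + 1e-9
    if saturated:
        t_hat = T_MAX
    info = {
        "loglik": -float(res.fun),
        "n_sites": int(sum(c.sum() for c in counts)),
        "saturated": bool(saturated),
    }
    return t_hat, info


def distance_matrix(alignment: PartitionedAlignment, method: str = "p",
                    deletion: str = "pairwise") -> DistanceMatrix:
    """All-pairs distance matrix over an alignment."""
    ids, rows = alignment.ids, alignment.rows
    n = len(ids)
    M = np.zeros((n, n))
    mask = complete_set_mask(rows) if deletion == "complete-set" else None
    saturated_pairs = []
    for i, j in itertools.combinations(range(n), 2):
        if method == "p":
            d, _ = p_distance(rows[i], rows[j], deletion=deletion, mask=mask)
        elif method == "ml":
            d, info = ml_distance(rows[i], rows[j], alignment.partitions)
            if info["saturated"]:
                saturated_pairs.append((ids[i], ids[j]))
        else:
            raise ValueError(f"unknown method {method!r}")
        M[i, j] = M[j, i] = d
    meta = {"deletion": deletion,
            "models": [p.model.kind for p in alignment.partitions],
            "optimizer_tol": _OPT_TOL if method == "ml" else None,
            "saturated_pairs": saturated_pairs}
    return DistanceMatrix(list(ids), M, method, meta)


# ---------------------------------------------------------------------------
# model parameter estimation (composite pairwise likelihood)


def observed_frequencies(rows) -> np.ndarray:
    counts = np.zeros(4)
    for r in rows:
        for ch in r.upper():
            i = BASE_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def _free_param_layout(kind: str):
    """Indices of free exchangeabilities relative to s_GT = 1."""
    if kind == "TVM":
        # s_AC, s_AG(=s_CT), s_AT, s_CG free; s_GT fixed
        return [("AC",), ("AG", "CT"), ("AT",), ("CG",)]
    if kind in ("SYM", "GTR"):
        return [("AC",), ("AG",), ("AT",), ("CG",), ("CT",)]
    return []  # JC


def _assemble(kind: str, free_vals, layout):
    s = {k: 1.0 for k in EXCH_KEYS}
    for keys, v in zip(layout, free_vals):
        for k in keys:
            s[k] = v
    return tuple(s[k] for k in EXCH_KEYS)


class _FastPairLikelihood:
    """Cached eigendecomposition for repeated two-sequence likelihoods."""

    def __init__(self, model: SubstitutionModel):
        from .models import _eigendecompose
        Q = build_rate_matrix(model)
        self.w, self.U, self.sqrt_pi = _eigendecompose(Q, model.pi)
        self.rates = model.rates()
        self.pi = model.pi

    def loglik(self, counts: np.ndarray, t: float) -> float:
        # P(t r_c) = D^{-1/2} U exp(w t r_c) U^T D^{1/2}, averaged over c
        expw = np.exp(np.outer(self.rates, self.w) * t)       # (C,4)
        E = np.einsum("ij,cj,kj->cik", self.U, expw, self.U)  # (C,4,4)
        P = E.mean(axis=0) * self.sqrt_pi[None, :] / self.sqrt_pi[:, None]
        site_prob = np.clip(self.pi[:, None] * P, 1e-300, None)
        return float(np.sum(counts * np.log(site_prob)))

    def ml_t(self, counts: np.ndarray) -> float:
        res = minimize_scalar(lambda t: -self.loglik(counts, t),
                              bounds=(T_MIN, T_MAX), method="bounded",
                              options={"xatol": 1e-7})
        return -res.fun


def estimate_model_params(rows, kind: str = "TVM", gamma: bool = True,
                          n_categories: int = 4, tol: float = 1e-6,
                          max_sweeps: int = 40) -> SubstitutionModel:
    """Fit exchangeabilities and gamma shape by composite pairwise likelihood.

    Maximizes the sum over all sequence pairs of the profile pairwise
    log-likelihood (each pair at its own optimal branch length),
    coordinate-wise on the log scale, starting from all exchangeabilities
    1 and alpha = 1.  Base frequencies are the observed proportions for
    ``+F`` kinds (TVM/GTR) and uniform for SYM/JC.  Degenerate input
    (fewer than two distinct rows) yields JC-like defaults.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 sequences")
    if len(set(rows)) < 2:
        return SubstitutionModel.jc(gamma_shape=1.0 if gamma else None,
                                    n_categories=n_categories)
    pi = (tuple(observed_frequencies(rows)) if kind in ("TVM", "GTR")
          else (0.25,) * 4)
    counts = [site_pattern_counts(a, b)
              for a, b in itertools.combinations(rows, 2)]
    layout = _free_param_layout(kind)
    free = np.ones(len(layout))
    alpha = 1.0

    def build(free_vals, a):
        return SubstitutionModel(kind, _assemble(kind, free_vals, layout), pi,
                                 gamma_shape=a if gamma else None,
                                 n_categories=n_categories)

    def objective(free_vals, a):
        ev = _FastPairLikelihood(build(free_vals, a))
        return sum(ev.ml_t(c) for c in counts)

    def coord_search(value, fn, lo, hi, halfwidth=1.5):
        """Bounded log-scale line search in a window around the current value."""
        lv = np.log(value)
        lo_w = max(lo, lv - halfwidth)
        hi_w = min(hi, lv + halfwidth)
        res = minimize_scalar(lambda x: -fn(np.exp(x)), bounds=(lo_w, hi_w),
                              method="bounded", options={"xatol": 1e-5})
        return float(np.exp(res.x)), -res.fun

    best = objective(free, alpha)
    for _ in range(max_sweeps):
        prev = best
        for k in range(len(free)):
            def fn_k(v, k=k):
                trial = free.copy()
                trial[k] = v
                return objective(trial, alpha)
            cand, val = coord_search(free[k], fn_k, np.log(1e-3), np.log(1e3))
            if val > best:
                free[k], best = cand, val
        if gamma:
            cand, val = coord_search(alpha, lambda a: objective(free, a),
                                     np.log(0.02), np.log(100.0))
            if val > best:
                alpha, best = cand, val
        if abs(best - prev) < tol * (1 + abs(prev)):
            break
    # joint simplex polish: coordinate descent converges slowly along the
    # exchangeability-scale / gamma-shape ridge
    from scipy.optimize import minimize

    def packed_neg(x):
        vals = np.exp(np.clip(x, np.log(1e-3), np.log(1e3)))
        if gamma:
            a = float(np.clip(vals[-1], 0.02, 100.0))
            return -objective(vals[:-1], a)
        return -objective(vals, alpha)

    x0 = np.log(np.concatenate([free, [alpha]]) if gamma else free)
    res = minimize(packed_neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": tol, "maxiter": 400})
    if -res.fun >= best:
        vals = np.exp(np.clip(res.x, np.log(1e-3), np.log(1e3)))
        if gamma:
            free, alpha = vals[:-1], float(np.clip(vals[-1], 0.02, 100.0))
        else:
            free = vals
    return build(free, alpha)


# ---------------------------------------------------------------------------
# group summaries


def group_distance_summary(dm: DistanceMatrix, groups: dict):
    """Mean intra-group and inter-group-pair distances.

    ``groups`` maps every id in ``dm`` to a group label.  Returns
    ``(intra, inter)``: ``intra`` maps group -> mean over unordered
    within-group pairs (groups with < 2 members are omitted); ``inter``
    maps frozenset({g1, g2}) -> mean over all cross pairs.
    """
    missing = [i for i in dm.ids if i not in groups]
    if missing:
        raise ValueError(f"unmapped ids: {', '.join(map(str, missing))}")
    intra_acc, inter_acc = {}, {}
    for (ia, a), (ib, b) in itertools.combinations(enumerate(dm.ids), 2):
        d = dm.matrix[ia, ib]
        ga, gb = groups[a], groups[b]
        key = ga if ga == gb else frozenset((ga, gb))
        acc = intra_acc if ga == gb else inter_acc
        acc.setdefault(key, []).append(d)
    intra = {g: float(np.mean(v)) for g, v in intra_acc.items()}
    inter = {k: float(np.mean(v)) for k, v in inter_acc.items()}
    return intra, inter


def summary_table(intra: dict, inter: dict) -> pd.DataFrame:
    """Long-format summary, distances rounded to 2 decimals for reporting."""
    rows = [{"group_1": g, "group_2": g, "kind": "intra",
             "mean_distance": round(v, 2)} for g, v in sorted(intra.items())]
    for key, v in sorted(inter.items(), key=lambda kv: sorted(kv[0])):
        g1, g2 = sorted(key)
        rows.append({"group_1": g1, "group_2": g2, "kind": "inter",
                     "mean_distance": round(v, 2)})
    return pd.DataFrame(rows, columns=["group_1", "group_2", "kind",
                                       "mean_distance"])


# ---------------------------------------------------------------------------
# partition table parsing


def parse_partition_file(text: str, models: dict | None = None):
    """Parse RAxML-style (``DNA, ITS1 = 1-826``) or TSV partition lines.

    ``models`` maps partition name -> SubstitutionModel; missing entries
    default to JC.  Returns a list of :class:`Partition`.
    """
    models = models or {}
    parts = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line:  # RAxML style
            left, rng = line.split("=", 1)
            name = left.split(",")[-1].strip()
            start, end = (int(x) for x in rng.strip().split("-"))
        else:  # TSV: name, start, end[, model kind]
            fields = line.split("\t")
            name, start, end = fields[0], int(fields[1]), int(fields[2])
        model = models.get(name, SubstitutionModel.jc())
        parts.append(Partition(name, start, end, model))
    if not parts:
        raise ValueError("no partitions found")
    return parts
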