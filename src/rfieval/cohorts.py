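"""Cohort analyses of prediction animals.

Groups candidates by shared male-line ancestry with the training population
(Group 1 shares sires, Group 2 only grandsires, Group 3 only
great-grandsires, Group 4 none), counts close genomic relatives (G >= 0.45,
i.e. first-degree allowing +/-0.05 estimation error), fits the
reliability-vs-relatives power curve, and cross-tabulates heifer vs cow
efficiency deciles to quantify re-ranking across life stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "assign_groups",
    "count_close_relatives",
    "fit_power_curve",
    "rank_cross_tab",
    "PowerCurveFit",
    "RankingCrossTab",
    "plot_reliability_curve",
]


def _male_line(pedigree: pd.DataFrame, include_maternal: bool):
    """Per-animal sets of sire / grandsires / great-grandsires.

    By default only sire-line male ancestors are walked (sire, paternal
    grandsire, paternal great-grandsire); ``include_maternal`` adds the
    maternal grandsire (sire of dam) and the corresponding great-grandsires.
    """
    sire = dict(zip(pedigree["animal"], pedigree["sire"]))
    dam = dict(zip(pedigree["animal"], pedigree["dam"]))

    def sires_of(ids):
        out = set()
        for a in ids:
            s = sire.get(a, 0)
            if s:
                out.add(s)
        return out

    def ancestry(a):
        s = sire.get(a, 0)
        if not s:
            return None
        tier1 = {s}
        tier2_parents = [s]
        if include_maternal:
            d = dam.get(a, 0)
            if d:
                tier2_parents.append(d)
        tier2 = sires_of(tier2_parents)
        if not tier2:
            return None
        tier3_parents = list(tier2)
        if include_maternal:
            for p in tier2_parents:
                d = dam.get(p, 0)
                if d:
                    tier3_parents.append(d)
        tier3 = sires_of(tier3_parents)
        if not tier3:
            return None
        return tier1, tier2, tier3

    return ancestry


def assign_groups(
    pedigree: pd.DataFrame,
    training_ids,
    candidate_ids,
    include_maternal: bool = False,
) -> tuple[pd.DataFrame, list]:
    """Assign candidates to relatedness Groups 1-4 against the training set.

    Group 1: candidate's sire is a training-animal sire.  Group 2: not
    Group 1, but a grandsire is shared with the training grandsires.
    Group 3: not Groups 1-2, but a great-grandsire is shared.  Group 4:
    no shared male-line ancestor within three generations.  Shared sets are
    compared as sets over the whole training population.  Candidates whose
    three-generation male-line ancestry cannot be resolved are excluded and
    returned separately.
    """
    ancestry = _male_line(pedigree, include_maternal)
    t_anc = [ancestry(a) for a in training_ids]
    t_anc = [a for a in t_anc if a is not None]
    t_sires = set().union(*(a[0] for a in t_anc)) if t_anc else set()
    t_gsires = set().union(*(a[1] for a in t_anc)) if t_anc else set()
    t_ggsires = set().union(*(a[2] for a in t_anc)) if t_anc else set()

    rows, unresolved = [], []
    for c in candidate_ids:
        anc = ancestry(c)
        if anc is None:
            unresolved.append(c)
            continue
        s, gs, ggs = anc
        if s & t_sires:
            grp, ev = 1, f"sire {sorted(s & t_sires)}"
        elif gs & t_gsires:
            grp, ev = 2, f"grandsire {sorted(gs & t_gsires)}"
        elif ggs & t_ggsires:
            grp, ev = 3, f"great-grandsire {sorted(ggs & t_ggsires)}"
        else:
            grp, ev = 4, "none shared"
        rows.append({"animal_id": c, "group": grp, "evidence": ev})
    return pd.DataFrame(rows, columns=["animal_id", "group", "evidence"]), unresolved


def count_close_relatives(G_cross, threshold: float = 0.45) -> np.ndarray:
    """Per candidate (row), count training animals (columns) with genomic
    relationship at or above ``threshold`` (inclusive: 0.45 counts)."""
    G_cross = np.atleast_2d(np.asarray(G_cross, dtype=float))
    return (G_cross >= threshold).sum(axis=1)


@dataclass
class PowerCurveFit:
    """rel = a * (n_relatives + 1)^b fitted by nonlinear least squares."""

    a: float
    b: float
    rss: float
    n_points: int

    def predict(self, counts) -> np.ndarray:
        return self.a * (np.asarray(counts, dtype=float) + 1.0) ** self.b


def fit_power_curve(reliabilities, relative_counts) -> PowerCurveFit:
    """Fit reliability as a power curve of the close-relative count.

    Uses rel = a·(n+1)^b (the +1 offset keeps zero-relative animals in the
    fit) with deterministic multi-start Levenberg-Marquardt; the best
    converged start by residual sum of squares wins.
    """
    from scipy.optimize import least_squares

    rel = np.asarray(reliabilities, dtype=float)
    cnt = np.asarray(relative_counts, dtype=float)
    if len(rel) < 3:
        raise ValueError("need at least 3 points")
    if (cnt < 0).any():
        raise ValueError("relative counts must be non-negative")
    x = cnt + 1.0

    def resid(p):
        return p[0] * x ** p[1] - rel

    starts = [
        (max(rel.mean(), 1e-3), 0.0),
        (max(rel.mean(), 1e-3), 0.3),
        (0.1, 0.5),
        (0.5, -0.2),
    ]
    best = None
    for a0, b0 in starts:
        sol = least_squares(resid, x0=[a0, b0], method="lm", max_nfev=10_000)
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("power-curve fit did not converge from any start")
    rss, (a, b) = best
    return PowerCurveFit(a=float(a), b=float(b), rss=rss, n_points=len(rel))


@dataclass
class RankingCrossTab:
    """Heifer-class x cow-class percentages (rows sum to 100)."""

    table: pd.DataFrame  # rows: heifer class, cols: cow class, percentages
    counts: pd.DataFrame
    cutoffs: tuple

    CLASSES = ("most", "medium", "least")


def _classify(values, ids, cutoffs) -> np.ndarray:
    """Efficiency classes by RFI breeding value: lowest values are 'most'
    efficient, highest are 'least'.  Class sizes are floor(n * cutoff) for
    the two extremes; ties resolved by stable animal-id order."""
    n = len(values)
    order = np.lexsort((np.asarray(ids), np.asarray(values)))
    n_most = int(np.floor(n * cutoffs[0]))
    n_least = int(np.floor(n * cutoffs[2]))
    cls = np.full(n, "medium", dtype=object)
    cls[order[:n_most]] = "most"
    if n_least:
        cls[order[-n_least:]] = "least"
    return cls


def rank_cross_tab(
    ebv_heifer: pd.Series,
    ebv_cow: pd.Series,
    cutoffs: tuple = (0.10, 0.80, 0.10),
) -> RankingCrossTab:
    """Cross-tabulate heifer vs cow efficiency classes.

    Both series are RFI breeding values indexed by animal id (lower = more
    efficient).  Animals are split into most / medium / least efficient by
    ``cutoffs`` for each life stage; the returned table gives, per heifer
    class (row), the percentage landing in each cow class.
    """
    if abs(sum(cutoffs) - 1.0) > 1e-9:
        raise ValueError("cutoffs must sum to 1")
    common = ebv_heifer.index.intersection(ebv_cow.index)
    if len(common) != len(ebv_heifer) or len(common) != len(ebv_cow):
        raise ValueError("both EBV vectors must cover the same animals")
    n = len(common)
    if int(np.floor(n * min(cutoffs[0], cutoffs[2]))) < 1:
        raise ValueError(f"{n} animals cannot resolve cutoffs {cutoffs}")
    ids = np.asarray(common)
    h_cls = _classify(ebv_heifer.loc[common].to_numpy(), ids, cutoffs)
    c_cls = _classify(ebv_cow.loc[common].to_numpy(), ids, cutoffs)
    classes = list(RankingCrossTab.CLASSES)
    counts = pd.crosstab(
        pd.Categorical(h_cls, categories=classes),
        pd.Categorical(c_cls, categories=classes),
        dropna=False,
    )
    counts.index.name = "heifer"
    counts.columns.name = "cow"
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return RankingCrossTab(table=pct, counts=counts, cutoffs=tuple(cutoffs))


def plot_reliability_curve(
    relative_counts, reliabilities, fit: PowerCurveFit | None = None, path=None, groups=None
):
    """Scatter of reliability vs close-relative count with the fitted curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    cnt = np.asarray(relative_counts, dtype=float)
    rel = np.asarray(reliabilities, dtype=float)
    if groups is not None:
        for g in np.unique(groups):
            m = np.asarray(groups) == g
            ax.scatter(cnt[m], rel[m], s=12, alpha=0.6, label=f"Group {g}")
        ax.legend(frameon=False)
    else:
        ax.scatter(cnt, rel, s=12, alpha=0.6)
    if fit is not None:
        xs = np.linspace(cnt.min(), cnt.max(), 200)
        ax.plot(xs, fit.predict(xs), "k-", lw=1.5)
    ax.set_xlabel("close relatives in training population (G ≥ 0.45)")
    ax.set_ylabel("reliability of GEBV")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
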