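"""Group comparisons and report generation for behavioural cohorts.

Behavioural summary metrics are typically non-normal across animals, so
group comparisons use nonparametric tests throughout: Shapiro-Wilk per
group (to document the non-normality), Levene's test for equality of
variances, Kruskal-Wallis as the omnibus test and pairwise Mann-Whitney U.
No multiple-testing correction is applied — this matches common practice
in behavioural phenotyping reports and is flagged in every result object.

Mode-occupancy contrasts use a Pearson chi-square on the 2 x k frame-count
table, with the per-mode contribution to the statistic identifying the
mode driving the difference. Speed-turn scatter distributions are compared
through their sorted Mahalanobis-distance curves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .modes import MISSING, Ethogram, ModeDistribution

__all__ = [
    "GroupTestResult",
    "ChiSquareModes",
    "MahalanobisProfile",
    "compare_groups",
    "chi_square_modes",
    "mahalanobis_profile",
    "polar_scatter_data",
    "render_report",
]


@dataclass
class GroupTestResult:
    """Nonparametric comparison of one summary metric across groups."""

    metric: str
    group_n: dict[str, int]
    shapiro_p: dict[str, float]
    levene_p: float
    kruskal_p: float
    pairwise_p: pd.DataFrame  # symmetric Mann-Whitney U p-value matrix
    multiple_testing_correction: str = "none"

    def __post_init__(self) -> None:
        M = self.pairwise_p.to_numpy(dtype=float)
        if not np.allclose(M, M.T, equal_nan=True):
            raise ValueError("pairwise p-value matrix must be symmetric")


@dataclass(frozen=True)
class ChiSquareModes:
    """Chi-square contrast of two mode distributions."""

    statistic: float
    dof: int
    p_value: float
    contributions: pd.Series  # per-mode share of the statistic
    largest_contributor: str

    def __post_init__(self) -> None:
        if abs(float(self.contributions.sum()) - self.statistic) > 1e-6:
            raise ValueError("contributions must sum to the statistic")


@dataclass
class MahalanobisProfile:
    """Sorted Mahalanobis-distance curves of per-group (speed, turn) clouds."""

    curves: dict[str, np.ndarray]  # ascending distances per group
    n_subsample: int


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def compare_groups(groups: dict[str, np.ndarray], metric: str = "") -> GroupTestResult:
    """Run the four-test nonparametric battery on one metric.

    ``groups`` maps group name to the per-animal metric values. Requires at
    least two groups with n >= 3 each.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has n < 3")
    names = list(arrays)
    shapiro_p = {g: float(stats.shapiro(v).pvalue) for g, v in arrays.items()}
    levene_p = float(stats.levene(*arrays.values()).pvalue)
    kruskal_p = float(stats.kruskal(*arrays.values()).pvalue)
    P = np.ones((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(
                stats.mannwhitneyu(
                    arrays[names[i]], arrays[names[j]], alternative="two-sided"
                ).pvalue
            )
            P[i, j] = P[j, i] = p
    return GroupTestResult(
        metric=metric,
        group_n={g: len(v) for g, v in arrays.items()},
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        kruskal_p=kruskal_p,
        pairwise_p=pd.DataFrame(P, index=names, columns=names),
    )


def _dist_counts(dist, group: str | None) -> pd.Series:
    if isinstance(dist, pd.Series):
        return dist
    if isinstance(dist, ModeDistribution):
        cols = list(dist.counts.columns)
        g = group if group is not None else cols[0]
        return dist.counts[g]
    raise TypeError("expected a ModeDistribution or a counts Series")


def chi_square_modes(dist_a, dist_b, group_a: str | None = None,
                     group_b: str | None = None) -> ChiSquareModes:
    """Pearson chi-square on the 2 x k mode frame-count table.

    Accepts :class:`~cionetho.modes.ModeDistribution` objects (optionally
    naming the group column) or raw count Series indexed by mode. Modes
    with zero expected count are dropped with a warning. The per-mode
    contribution sums (O-E)^2/E over the mode's two cells; the largest
    contributor is the mode driving the difference.
    """
    a = _dist_counts(dist_a, group_a)
    b = _dist_counts(dist_b, group_b)
    modes = a.index.union(b.index, sort=False)
    a = a.reindex(modes, fill_value=0).astype(float)
    b = b.reindex(modes, fill_value=0).astype(float)
    keep = (a + b) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} mode(s) with zero expected count")
        a, b = a[keep], b[keep]
    table = np.vstack([a.to_numpy(), b.to_numpy()])
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    contrib_cells = (table - expected) ** 2 / expected
    contributions = pd.Series(contrib_cells.sum(axis=0), index=a.index)
    return ChiSquareModes(
        statistic=float(chi2),
        dof=int(dof),
        p_value=float(p),
        contributions=contributions,
        largest_contributor=str(contributions.idxmax()),
    )


# ---------------------------------------------------------------------------
# Distribution comparisons on (speed, turn) clouds
# ---------------------------------------------------------------------------

def _subsample_rows(X: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    if len(X) <= n:
        return X
    return X[rng.choice(len(X), size=n, replace=False)]


def mahalanobis_profile(
    groups: dict[str, np.ndarray], n: int = 100_000, seed: int = 0
) -> MahalanobisProfile:
    """Sorted Mahalanobis distances of each group's observations.

    Each group supplies an (m, d) array of (rho, dtheta) observations
    (m >= 3). Distances are measured from the group mean under the group
    covariance (regularised by 1e-9 x trace on the diagonal when
    near-singular) and returned sorted ascending.
    """
    rng = np.random.default_rng(seed)
    curves: dict[str, np.ndarray] = {}
    for g, X in groups.items():
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < 3:
            raise ValueError(f"group {g!r} needs an (m >= 3, d) observation array")
        X = _subsample_rows(X, n, rng)
        mu = X.mean(axis=0)
        cov = np.cov(X, rowvar=False)
        if np.linalg.cond(cov) > 1e12:
            cov = cov + 1e-9 * np.trace(cov) * np.eye(cov.shape[0])
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular covariance in group {g!r}") from err
        d = X - mu
        dist = np.sqrt(np.einsum("ij,jk,ik->i", d, inv, d))
        curves[g] = np.sort(dist)
    return MahalanobisProfile(curves=curves, n_subsample=n)


def polar_scatter_data(
    speed_turn: np.ndarray, n: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Seeded uniform subsample (without replacement) of (speed, turn) rows.

    Returns all rows when fewer than ``n`` are available.
    """
    X = np.asarray(speed_turn, dtype=float)
    return _subsample_rows(X, n, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def render_report(
    outdir,
    summaries: list,
    ethograms: dict[str, Ethogram] | None = None,
    distribution: ModeDistribution | None = None,
    polar: dict[str, np.ndarray] | None = None,
    params: dict | None = None,
    make_figures: bool = True,
) -> Path:
    """Write the analysis bundle: CSV tables, figures and a run manifest.

    The manifest records every analysis parameter (filter cutoff,
    activity threshold, feature window, lag, seeds, ...) so a run can be
    reproduced bit-for-bit; tables are sorted for byte-identical re-runs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    rows = [
        {
            "animal_id": s.animal_id,
            "median_speed_um_s": s.median_speed,
            "max_speed_um_s": s.max_speed,
            "AC": s.AC,
            "min_complexity_bits": s.min_complexity,
            "TTO": s.TTO,
            "TDO": s.TDO,
            "median_dist_centre_mm": s.median_dist_centre,
        }
        for s in summaries
    ]
    pd.DataFrame(rows).sort_values("animal_id").to_csv(out / "summaries.csv", index=False)

    if ethograms:
        parts = [
            pd.DataFrame(
                {"animal_id": e.animal_id, "frame": np.arange(e.n_frames), "mode": e.labels}
            )
            for e in (ethograms[a] for a in sorted(ethograms))
        ]
        pd.concat(parts, ignore_index=True).to_csv(out / "ethograms.csv", index=False)

    if distribution is not None:
        distribution.fractions.rename_axis("mode").to_csv(out / "mode_distribution.csv")

    manifest = {
        "parameters": {
            "filter_cutoff_hz": 1.0,
            "activity_threshold_um_s": 200.0,
            "lag_frames": 5,
            "feature_half_window_frames": 25,
            "complexity_window_s": 3.0,
            **(params or {}),
        },
        "n_animals": len(summaries),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if make_figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ethograms:
            ids = sorted(ethograms)
            all_modes = sorted(
                {m for e in ethograms.values() for m in np.unique(e.labels)} - {MISSING}
            )
            cmap = matplotlib.colormaps["viridis"].resampled(max(len(all_modes), 2))
            fig, ax = plt.subplots(figsize=(8, 0.4 * len(ids) + 1))
            for yi, aid in enumerate(ids):
                lab = ethograms[aid].labels
                img = np.array(
                    [all_modes.index(m) if m != MISSING else -1 for m in lab]
                )
                colors = np.zeros((len(img), 3))
                for ci, mname in enumerate(all_modes):
                    colors[img == ci] = cmap(ci)[:3]
                ax.imshow(
                    colors[None, :, :], aspect="auto",
                    extent=(0, len(lab), yi, yi + 1),
                )
            ax.set_xlabel("frame")
            ax.set_ylabel("animal")
            ax.set_yticks([])
            fig.savefig(out / "ethograms.png", dpi=100)
            plt.close(fig)

        if polar:
            fig, axes = plt.subplots(
                1, len(polar), subplot_kw={"projection": "polar"},
                figsize=(4 * len(polar), 4), squeeze=False,
            )
            for ax, (g, X) in zip(axes[0], polar.items()):
                ax.scatter(X[:, 1], X[:, 0], s=1, alpha=0.2)
                ax.set_title(g)
            fig.savefig(out / "polar_scatter.png", dpi=100)
            plt.close(fig)

    return out
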