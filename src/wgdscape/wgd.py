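"""WGD detection and dating from Ks distributions.

A whole-genome duplication leaves a burst of paralog pairs with a common
origin time, visible as a mode in the paranome Ks distribution.  This
module fits a Gaussian mixture to ln(Ks) (Ks modes are approximately
lognormal), selects the number of components by BIC, converts component
parameters back to Ks-scale density modes, calibrates the synonymous
substitution rate r from an ortholog comparison with a known divergence
time (r = Ks_ortholog / 2T), and dates each WGD as T = Ks_mode / (2 r).

A kernel-density local-maxima list is emitted alongside the mixture as an
estimator-independent cross-check on the peak positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .kaks import KsRecord

__all__ = [
    "KsMixture",
    "RateCalibration",
    "WGDEvent",
    "fit_ks_mixture",
    "calibrate_rate",
    "date_wgd",
    "assign_pairs_to_wgd",
    "enrich_gene_sets",
    "fraction_pct",
]


@dataclass(frozen=True)
class KsMixture:
    """A lognormal mixture fitted to a Ks sample.

    ``components`` holds (weight, mean of ln Ks, sd of ln Ks) sorted by
    ascending Ks-scale mode; ``modes`` are the Ks-scale density modes
    exp(mu - sigma^2) of each component.
    """

    components: tuple[tuple[float, float, float], ...]
    modes: tuple[float, ...]
    n_fitted: int
    bic_by_k: dict[int, float]
    kde_modes: tuple[float, ...] = ()
    ks_window: tuple[float, float] = (0.005, 2.0)

    def __post_init__(self) -> None:
        total = sum(w for w, _, _ in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {total}, not 1")
        if list(self.modes) != sorted(self.modes):
            raise ValueError("modes must be ascending")

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def dominant_index(self) -> int:
        return max(range(self.k), key=lambda i: self.components[i][0])

    @property
    def dominant_mode(self) -> float:
        return self.modes[self.dominant_index]


@dataclass(frozen=True)
class RateCalibration:
    """Synonymous substitution rate from an ortholog Ks and divergence time."""

    rate_r: float  # substitutions / synonymous site / year
    ortholog_ks_mode: float
    divergence_time_T: float  # years

    def __post_init__(self) -> None:
        expect = self.ortholog_ks_mode / (2.0 * self.divergence_time_T)
        if not np.isclose(self.rate_r, expect, rtol=1e-12):
            raise ValueError("rate_r must equal ortholog_ks_mode / (2 T)")


@dataclass(frozen=True)
class WGDEvent:
    ks_mode: float
    date_mya: float
    component_index: int
    assigned_pairs: tuple[str, ...] = ()


def fit_ks_mixture(
    ks_values: Sequence[float] | np.ndarray,
    ks_min: float = 0.005,
    ks_max: float = 2.0,
    k_range: Iterable[int] = (1, 2, 3, 4),
    seed: int = 0,
    n_init: int = 5,
) -> KsMixture:
    """Fit a Gaussian mixture to ln(Ks) with BIC model selection.

    Only finite values in (ks_min, ks_max] enter the fit; fewer than 100
    usable values, or a degenerate (zero-variance) sample, is an error.
    """
    ks = np.asarray([k for k in ks_values if k is not None], dtype=float)
    ks = ks[np.isfinite(ks)]
    ks = ks[(ks > ks_min) & (ks <= ks_max)]
    if ks.size < 100:
        raise ValueError(f"insufficient data: {ks.size} usable Ks values (< 100)")
    log_ks = np.log(ks).reshape(-1, 1)
    if np.ptp(log_ks) == 0:
        raise ValueError("degenerate Ks sample: all values identical")

    bic_by_k: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in k_range:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            reg_covar=1e-6,
        ).fit(log_ks)
        bic_by_k[k] = float(gm.bic(log_ks))
        fits[k] = gm
    best_k = min(bic_by_k, key=lambda k: (bic_by_k[k], k))
    gm = fits[best_k]

    comps = []
    for w, mu, var in zip(
        gm.weights_, gm.means_.ravel(), gm.covariances_.reshape(-1)
    ):
        comps.append((float(w), float(mu), float(np.sqrt(var))))
    # Ks-scale density mode of a lognormal component: exp(mu - sigma^2)
    comps.sort(key=lambda c: np.exp(c[1] - c[2] ** 2))
    modes = tuple(float(np.exp(mu - sd**2)) for _, mu, sd in comps)

    # KDE cross-check on the Ks scale
    kde = stats.gaussian_kde(ks)
    grid = np.linspace(ks.min(), ks.max(), 512)
    dens = kde(grid)
    is_max = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    kde_modes = tuple(float(x) for x in grid[1:-1][is_max])

    return KsMixture(
        components=tuple(comps),
        modes=modes,
        n_fitted=int(ks.size),
        bic_by_k=bic_by_k,
        kde_modes=kde_modes,
        ks_window=(ks_min, ks_max),
    )


def calibrate_rate(ortholog_ks_mode: float, divergence_time_years: float) -> RateCalibration:
    """r = Ks_ortholog / (2 T): substitutions per synonymous site per year."""
    if ortholog_ks_mode <= 0 or divergence_time_years <= 0:
        raise ValueError("ortholog Ks and divergence time must be positive")
    return RateCalibration(
        rate_r=ortholog_ks_mode / (2.0 * divergence_time_years),
        ortholog_ks_mode=ortholog_ks_mode,
        divergence_time_T=divergence_time_years,
    )


def date_wgd(ks_mode: float, rate_r: float) -> float:
    """Date a WGD in MYA: T = Ks_mode / (2 r) / 1e6."""
    if rate_r <= 0:
        raise ValueError("rate_r must be positive")
    if ks_mode < 0:
        raise ValueError("ks_mode must be non-negative")
    return ks_mode / (2.0 * rate_r) / 1e6


def _responsibilities(log_ks: np.ndarray, mixture: KsMixture) -> np.ndarray:
    """Posterior responsibility of each component for each ln(Ks) value."""
    dens = np.stack(
        [
            w * stats.norm.pdf(log_ks, loc=mu, scale=sd)
            for w, mu, sd in mixture.components
        ],
        axis=1,
    )
    total = dens.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return dens / total


def assign_pairs_to_wgd(
    ks_records: Sequence[KsRecord],
    mixture: KsMixture,
    total_genes: int | None = None,
) -> dict:
    """Assign each pair to the mixture component with maximal posterior.

    Returns a dict with ``assignments`` (component index -> list of
    "geneA|geneB" pair ids), ``posteriors`` (DataFrame), ``n_unassigned``
    (pairs with undefined Ks), and ``retention`` — per-component distinct
    retained-gene counts, with fraction of ``total_genes`` when given.
    """
    defined = [r for r in ks_records if r.ks is not None and r.ks > 0]
    n_unassigned = len(ks_records) - len(defined)
    assignments: dict[int, list[str]] = {i: [] for i in range(mixture.k)}
    rows = []
    if defined:
        log_ks = np.log([r.ks for r in defined])
        resp = _responsibilities(log_ks, mixture)
        comp = resp.argmax(axis=1)
        for r, c, post in zip(defined, comp, resp):
            pair_id = f"{r.gene_a}|{r.gene_b}"
            assignments[int(c)].append(pair_id)
            rows.append(
                dict(pair=pair_id, ks=r.ks, component=int(c), posterior=float(post[c]))
            )
    retention = []
    for i in range(mixture.k):
        genes = set()
        for pid in assignments[i]:
            a, b = pid.split("|")
            genes.update((a, b))
        entry = dict(
            component=i,
            ks_mode=mixture.modes[i],
            n_pairs=len(assignments[i]),
            n_genes=len(genes),
        )
        if total_genes:
            entry["fraction_of_genes_pct"] = fraction_pct(len(genes), total_genes)
        retention.append(entry)
    return dict(
        assignments=assignments,
        posteriors=pd.DataFrame(rows, columns=["pair", "ks", "component", "posterior"]),
        n_unassigned=n_unassigned,
        retention=pd.DataFrame(retention),
    )


def fraction_pct(count: int, total: int) -> float:
    """Percentage of ``total``, rounded to one decimal (report convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


def enrich_gene_sets(
    gene_list: Iterable[str],
    universe: Iterable[str],
    gene_set_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Over-representation test per gene set: one-sided hypergeometric tail
    with Benjamini-Hochberg q-values across sets.

    ``gene_set_map`` maps set name -> member genes; membership outside the
    universe is ignored.  Returns a DataFrame sorted by p-value.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    hits = set(gene_list) & universe_set
    if set(gene_list) - universe_set:
        raise ValueError("gene_list contains genes outside the universe")
    M = len(universe_set)
    N = len(hits)
    rows = []
    for name, members in gene_set_map.items():
        in_set = set(members) & universe_set
        K = len(in_set)
        k = len(in_set & hits)
        # P(X >= k) for X ~ Hypergeom(M, K, N)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append(dict(gene_set=name, set_size=K, overlap=k, p_value=min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p_value"])
    if len(df):
        df["q_value"] = stats.false_discovery_control(df["p_value"].to_numpy(), method="bh")
    else:
        df["q_value"] = []
    return df.sort_values(["p_value", "gene_set"], ignore_index=True)
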