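"""Monte-Carlo null models for immunogold point patterns.

Two nulls are provided:

* **random simulation** — particles placed uniformly in the ROI under a
  10-nm hard-core constraint (no two pre-displacement positions closer than
  10 nm, mimicking gold-particle exclusion), then each shifted by a vector
  drawn uniformly from a 30-nm-diameter disk to reproduce the positional
  offset introduced by the probe/antibody sandwich (label displacement).

* **fitted simulation** — the observed pattern is modeled as a Matérn
  cluster process (Poisson parents, each spawning a Poisson number of
  offspring uniform in a disk), fitted by minimum contrast on Ripley's K;
  candidate simulations are accepted only if two-sample Kolmogorov–Smirnov
  tests on both the all-pairwise-distance (APD) and nearest-neighbor-
  distance (NND) distributions yield p >= 0.1 against the observed pattern.
  To avoid excessive power at large sample sizes the KS p-value is a
  parametric bootstrap: 100-value subsamples of the simulated distances are
  tested against the real empirical CDF, 1000 times, and the p-values
  averaged.

Comparison drivers pair real and simulated summary statistics per replicate
(mean NND, subregion density, mean CPI, cross-channel NND) as tidy tables
for downstream (external) statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from scipy.special import kolmogorov
from scipy.stats import ks_2samp

from replipat.geometry import (
    ParticleSet,
    RimSpec,
    RoiPolygon,
    _contains_mask,
    particle_density,
    polygon_area,
)
from replipat.point_stats import (
    DistanceSample,
    all_pairwise_distances,
    cpi,
    nnd_cross,
    nnd_same,
)
from replipat.sampling import as_rng, sample_uniform_in_polygon

__all__ = [
    "RandomSimConfig",
    "MaternParams",
    "GofResult",
    "FittedSimulationError",
    "place_hardcore",
    "displace_disk",
    "simulate_random",
    "ripley_k",
    "matern_k_theoretical",
    "fit_matern",
    "simulate_matern",
    "ks_bootstrap_p",
    "fitted_simulation",
    "compare_real_vs_sim_nnd",
    "subregion_density_vs_random",
    "cpi_vs_random",
    "association_vs_fitted",
]


@dataclass(frozen=True)
class RandomSimConfig:
    """Parameters of the hard-core random simulation.

    ``min_distance`` is the pre-displacement hard-core distance in nm;
    ``displacement_diameter`` the diameter (nm) of the disk within which each
    particle is uniformly shifted to model label displacement.
    """

    min_distance: float = 10.0
    displacement_diameter: float = 30.0
    n_replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_distance < 0 or self.displacement_diameter < 0:
            raise ValueError("distances must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class MaternParams:
    """Matérn cluster process parameters: parent intensity ``kappa``
    (parents/µm²), cluster ``radius`` (nm), mean offspring count ``mu``.

    ``degenerate`` flags fits indistinguishable from an unclustered pattern
    (offspring count near 1 or cluster radius on the ROI scale)."""

    kappa: float
    radius: float
    mu: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.radius <= 0 or self.mu <= 0:
            raise ValueError("Matérn parameters must be > 0")

    @property
    def intensity_per_um2(self) -> float:
        return self.kappa * self.mu


@dataclass(frozen=True)
class GofResult:
    """Goodness-of-fit of one simulated pattern against the observed one.

    A simulation is accepted when the bootstrap KS p-values for both the
    all-pairwise-distance and nearest-neighbor-distance distributions are
    at least 0.1."""

    p_apd: float
    p_nnd: float
    n_bootstrap: int = 1000
    accepted: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "accepted", self.p_apd >= 0.1 and self.p_nnd >= 0.1
        )


class FittedSimulationError(RuntimeError):
    """No simulation was accepted within the attempt budget; carries the
    best attempt's goodness-of-fit."""

    def __init__(self, msg: str, best: GofResult | None,
                 best_pattern: ParticleSet | None = None):
        super().__init__(msg)
        self.best = best
        self.best_pattern = best_pattern


# ---------------------------------------------------------------------------
# random simulation


def place_hardcore(
    roi: RoiPolygon,
    n_points: int,
    min_distance: float,
    rng=None,
    max_attempts_per_point: int = 10_000,
) -> np.ndarray:
    """Sequential random placement (RSA) of ``n_points`` uniform points in the
    ROI with all pairwise distances >= ``min_distance``.

    Raises if the packing is infeasible within the attempt budget, reporting
    the density at which placement stalled.
    """
    rng = as_rng(rng)
    pts = np.empty((n_points, 2))
    tree_pts: list[np.ndarray] = []
    placed = 0
    attempts = 0
    while placed < n_points:
        cand = sample_uniform_in_polygon(roi, 1, rng)[0]
        ok = True
        if min_distance > 0 and placed:
            d2 = np.sum((pts[:placed] - cand) ** 2, axis=1)
            ok = bool(np.min(d2) >= min_distance**2)
        if ok:
            pts[placed] = cand
            placed += 1
            attempts = 0
        else:
            attempts += 1
            if attempts >= max_attempts_per_point:
                dens = placed / polygon_area(roi) * 1e6
                raise ValueError(
                    f"hard-core packing infeasible: stalled at {placed}/"
                    f"{n_points} points ({dens:.1f}/um^2) with "
                    f"min_distance={min_distance} nm"
                )
    return pts


def displace_disk(points: np.ndarray, diameter: float, rng=None) -> np.ndarray:
    """Shift each point by a vector uniform over a disk of the given diameter
    (area-uniform: radius proportional to sqrt(u))."""
    rng = as_rng(rng)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if diameter == 0 or len(pts) == 0:
        return pts.copy()
    r = (diameter / 2.0) * np.sqrt(rng.uniform(size=len(pts)))
    th = rng.uniform(0, 2 * np.pi, size=len(pts))
    return pts + np.column_stack([r * np.cos(th), r * np.sin(th)])


def simulate_random(
    roi: RoiPolygon,
    n_points: int,
    cfg: RandomSimConfig = RandomSimConfig(),
    rng=None,
) -> ParticleSet:
    """One replicate of the hard-core random simulation: uniform placement
    with the hard core, then label displacement.

    Displaced points are not clipped back into the ROI (the label may cross
    the demarcation line); density comparisons always re-count within the
    ROI.
    """
    rng = as_rng(cfg.seed if rng is None else rng)
    pts = place_hardcore(roi, n_points, cfg.min_distance, rng)
    shifted = displace_disk(pts, cfg.displacement_diameter, rng)
    return ParticleSet(shifted, channel="sim_random", roi_id=roi.id)


# ---------------------------------------------------------------------------
# Matérn cluster process: K function, fitting, simulation


def ripley_k(
    points: np.ndarray, roi: RoiPolygon, r: np.ndarray
) -> np.ndarray:
    """Border-corrected (minus-sampling) estimate of Ripley's K at radii ``r``.

    Only points farther than r from the ROI boundary contribute as reference
    points, removing edge bias at the cost of variance.
    """
    import shapely

    pts = np.atleast_2d(points)
    n = len(pts)
    area = polygon_area(roi)
    lam = n / area
    b = shapely.distance(roi.polygon.exterior, shapely.points(pts))
    D = squareform(pdist(pts))
    out = np.empty(len(r))
    for j, rj in enumerate(r):
        ref = b > rj
        nref = int(ref.sum())
        if nref == 0:
            out[j] = np.nan
            continue
        counts = (D[ref] <= rj).sum() - nref  # exclude self-pairs
        out[j] = counts / (lam * nref)
    return out


def matern_k_theoretical(r: np.ndarray, kappa_nm2: float, radius: float) -> np.ndarray:
    """K function of a Matérn cluster process with parent intensity
    ``kappa_nm2`` (per nm²) and cluster radius ``radius`` (nm)."""
    r = np.asarray(r, dtype=float)
    z = np.minimum(r / (2.0 * radius), 1.0)
    with np.errstate(invalid="ignore"):
        h = 2.0 + (1.0 / np.pi) * (
            (8 * z**2 - 4) * np.arccos(z)
            - 2 * np.arcsin(z)
            + 4 * z * np.sqrt((1 - z**2) ** 3)
            - 6 * z * np.sqrt(1 - z**2)
        )
    h = np.where(r >= 2.0 * radius, 1.0, h)
    return np.pi * r**2 + h / kappa_nm2


def fit_matern(ps: ParticleSet, roi: RoiPolygon) -> MaternParams:
    """Fit a Matérn cluster process to an observed pattern by minimum
    contrast on Ripley's K (exponent 1/4, radii up to a quarter of the ROI
    diameter), with total intensity constrained to the observed n/area.

    Returns parameters with ``kappa * mu * area = n`` exactly; the
    ``degenerate`` flag marks fits with mu near 1 or radius on the ROI scale
    (no real clustering detected).
    """
    n = len(ps)
    if n < 10:
        raise ValueError("fit_matern needs at least 10 points")
    if np.allclose(pdist(ps.points), 0):
        raise ValueError("degenerate pattern: all points coincident")
    area = polygon_area(roi)
    lam = n / area  # per nm^2
    minx, miny, maxx, maxy = roi.polygon.bounds
    diam = float(np.hypot(maxx - minx, maxy - miny))
    # cap the contrast radii near the informative (cluster-scale) range:
    # at large r the border-corrected K has few reference points and its
    # noise would dominate the contrast
    rmax = min(diam / 4.0, 8.0 * nnd_same(ps).mean)
    r = np.linspace(rmax / 50.0, rmax, 50)
    k_emp = ripley_k(ps.points, roi, r)
    ok = np.isfinite(k_emp)
    r, k_emp = r[ok], k_emp[ok]
    k_emp_q = k_emp**0.25

    def contrast(log_params: np.ndarray) -> float:
        log_kappa, log_radius = log_params
        kq = matern_k_theoretical(r, math.exp(log_kappa), math.exp(log_radius)) ** 0.25
        return float(np.sum((k_emp_q - kq) ** 2))

    # coarse grid then Nelder-Mead polish
    best = None
    for mu0 in (2.0, 5.0, 10.0, 20.0, 40.0):
        for r0 in np.geomspace(5.0, rmax, 8):
            x0 = np.array([math.log(lam / mu0), math.log(r0)])
            val = contrast(x0)
            if best is None or val < best[1]:
                best = (x0, val)
    res = minimize(contrast, best[0], method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 500})
    kappa_nm2 = math.exp(res.x[0])
    radius = math.exp(res.x[1])
    mu = lam / kappa_nm2
    degenerate = mu <= 1.5 or radius >= diam / 2.0
    return MaternParams(
        kappa=kappa_nm2 * 1e6, radius=radius, mu=mu, degenerate=degenerate
    )


def simulate_matern(
    params: MaternParams, roi: RoiPolygon, rng=None
) -> ParticleSet:
    """Simulate a Matérn cluster pattern clipped to the ROI.

    Parents are Poisson in the ROI buffered by the cluster radius (so
    clusters straddling the border contribute), each spawning a Poisson(mu)
    number of offspring uniform in its disk; offspring outside the ROI are
    discarded.
    """
    rng = as_rng(rng)
    buffered = roi.polygon.buffer(params.radius)
    kappa_nm2 = params.kappa * 1e-6
    n_parents = rng.poisson(kappa_nm2 * buffered.area)
    if n_parents == 0:
        return ParticleSet(np.empty((0, 2)), channel="sim_matern", roi_id=roi.id)
    parents = sample_uniform_in_polygon(buffered, n_parents, rng)
    counts = rng.poisson(params.mu, size=n_parents)
    total = int(counts.sum())
    if total == 0:
        return ParticleSet(np.empty((0, 2)), channel="sim_matern", roi_id=roi.id)
    centers = np.repeat(parents, counts, axis=0)
    rr = params.radius * np.sqrt(rng.uniform(size=total))
    th = rng.uniform(0, 2 * np.pi, size=total)
    pts = centers + np.column_stack([rr * np.cos(th), rr * np.sin(th)])
    keep = _contains_mask(pts, roi, None)
    return ParticleSet(pts[keep], channel="sim_matern", roi_id=roi.id)


# ---------------------------------------------------------------------------
# goodness of fit


def _values(sample) -> np.ndarray:
    return sample.values if isinstance(sample, DistanceSample) else \
        np.asarray(sample, dtype=float).ravel()


def ks_bootstrap_p(
    real, sim, n_sub: int = 100, n_rep: int = 1000, rng=None
) -> float:
    """Two-sample KS p-value between a real and a simulated distance sample,
    bootstrapped to avoid excessive power at large sample sizes.

    If the simulated sample has at most ``n_sub`` values a single KS test is
    performed; otherwise ``n_rep`` subsamples of ``n_sub`` values (without
    replacement) are each tested against the real sample and the p-values
    averaged. The result is invariant to the input ordering.
    """
    rng = as_rng(rng)
    real_v = np.sort(_values(real))
    sim_v = np.sort(_values(sim))
    if real_v.size == 0 or sim_v.size == 0:
        raise ValueError("ks_bootstrap_p needs nonempty samples")
    if sim_v.size <= n_sub:
        return float(ks_2samp(real_v, sim_v).pvalue)
    n = real_v.size
    idx = np.stack(
        [rng.choice(sim_v.size, n_sub, replace=False) for _ in range(n_rep)]
    )
    subs = np.sort(sim_v[idx], axis=1)
    # two-sample KS statistic of each subsample against the real ECDF,
    # evaluated at the subsample's jump points from both sides
    cr = np.searchsorted(real_v, subs, side="right") / n
    cl = np.searchsorted(real_v, subs, side="left") / n
    i = np.arange(1, n_sub + 1)
    d = np.maximum(
        np.abs(cr - i / n_sub).max(axis=1),
        np.abs(cl - (i - 1) / n_sub).max(axis=1),
    )
    # asymptotic Kolmogorov p with Stephens' small-sample correction
    en = math.sqrt(n * n_sub / (n + n_sub))
    p = kolmogorov((en + 0.12 + 0.11 / en) * d)
    return float(p.mean())


def fitted_simulation(
    ps: ParticleSet,
    roi: RoiPolygon,
    max_attempts: int = 100,
    rng=None,
    params: MaternParams | None = None,
    n_bootstrap: int = 1000,
) -> tuple[ParticleSet, GofResult]:
    """Fitted Monte-Carlo simulation: draw Matérn patterns from the (single)
    fit until one is accepted by the KS criterion (p >= 0.1 for both APD and
    NND), or raise :class:`FittedSimulationError` carrying the best attempt.

    ``params`` may be supplied to reuse a fit across replicates.
    """
    rng = as_rng(rng)
    if params is None:
        params = fit_matern(ps, roi)
    real_nnd = nnd_same(ps)
    real_apd = all_pairwise_distances(ps)
    best: GofResult | None = None
    best_pattern = None
    for _ in range(max_attempts):
        sim = simulate_matern(params, roi, rng)
        if len(sim) < 2:
            continue
        p_apd = ks_bootstrap_p(real_apd, all_pairwise_distances(sim),
                               n_rep=n_bootstrap, rng=rng)
        p_nnd = ks_bootstrap_p(real_nnd, nnd_same(sim),
                               n_rep=n_bootstrap, rng=rng)
        gof = GofResult(p_apd=p_apd, p_nnd=p_nnd, n_bootstrap=n_bootstrap)
        if best is None or min(gof.p_apd, gof.p_nnd) > min(best.p_apd, best.p_nnd):
            best, best_pattern = gof, sim
        if gof.accepted:
            return sim, gof
    raise FittedSimulationError(
        f"no accepted simulation within {max_attempts} attempts "
        f"(best p_apd={best.p_apd:.3f}, p_nnd={best.p_nnd:.3f})"
        if best is not None
        else f"no nonempty simulation within {max_attempts} attempts",
        best,
        best_pattern,
    )


# ---------------------------------------------------------------------------
# real-vs-simulated comparison drivers


def compare_real_vs_sim_nnd(
    ps: ParticleSet,
    roi: RoiPolygon,
    null_kind: str = "random",
    cfg: RandomSimConfig = RandomSimConfig(),
    n_replicates: int = 100,
    rng=None,
) -> pd.DataFrame:
    """Pair the observed mean NND with the mean NND of ``n_replicates`` null
    simulations (``random`` or ``fitted``); one row per replicate, for
    external statistics."""
    if null_kind not in ("random", "fitted"):
        raise ValueError("null_kind must be 'random' or 'fitted'")
    rng = as_rng(rng)
    real_mean = nnd_same(ps).mean
    params = fit_matern(ps, roi) if null_kind == "fitted" else None
    rows = []
    for rep in range(n_replicates):
        if null_kind == "random":
            sim = simulate_random(roi, len(ps), cfg, rng=rng)
        else:
            sim, _ = fitted_simulation(ps, roi, rng=rng, params=params)
        rows.append(
            {"roi_id": roi.id, "replicate": rep, "real_mean_nnd": real_mean,
             "sim_mean_nnd": nnd_same(sim).mean}
        )
    return pd.DataFrame(rows)


def subregion_density_vs_random(
    ps: ParticleSet,
    bouton_roi: RoiPolygon,
    az_roi: RoiPolygon,
    rim: RimSpec = RimSpec(),
    cfg: RandomSimConfig = RandomSimConfig(),
    n_replicates: int = 100,
    rng=None,
) -> pd.DataFrame:
    """Observed vs null particle density (per µm², rim rule applied) in a
    subregion (e.g. the active zone of a bouton), where the null randomizes
    the same number of particles over the whole parent region."""
    if not bouton_roi.polygon.covers(az_roi.polygon):
        raise ValueError("the AZ ROI must lie inside the bouton ROI")
    rng = as_rng(rng)
    real = particle_density(ps, az_roi, rim)
    rows = []
    for rep in range(n_replicates):
        sim = simulate_random(bouton_roi, len(ps), cfg, rng=rng)
        sim_ps = ParticleSet(sim.points, channel=ps.channel, roi_id=az_roi.id)
        rows.append(
            {"roi_id": az_roi.id, "replicate": rep, "real_density": real,
             "sim_density": particle_density(sim_ps, az_roi, rim)}
        )
    return pd.DataFrame(rows)


def cpi_vs_random(
    ps: ParticleSet,
    roi: RoiPolygon,
    n_replicates: int = 100,
    rng=None,
    rim: RimSpec | None = None,
) -> tuple[float, np.ndarray]:
    """Observed mean CPI against the Monte-Carlo distribution of mean CPI
    under uniform randomization of the same number of particles within the
    ROI."""
    if len(ps) == 0:
        raise ValueError("cpi_vs_random needs at least one particle")
    rng = as_rng(rng)
    real = cpi(ps, roi, rim=rim).mean_cpi
    sims = np.empty(n_replicates)
    for rep in range(n_replicates):
        pts = sample_uniform_in_polygon(roi, len(ps), rng)
        sims[rep] = cpi(
            ParticleSet(pts, channel="sim", roi_id=roi.id), roi
        ).mean_cpi
    return real, sims


def association_vs_fitted(
    channel_a: ParticleSet,
    channel_b: ParticleSet,
    roi: RoiPolygon,
    n_replicates: int = 100,
    rng=None,
    max_attempts: int = 100,
) -> pd.DataFrame:
    """Cross-channel association test: the mean NND from channel A to channel
    B, compared with the same statistic after replacing channel A by fitted
    Matérn simulations (channel B held fixed). One row per replicate."""
    if len(channel_a) == 0 or len(channel_b) == 0:
        raise ValueError("both channels must be nonempty")
    rng = as_rng(rng)
    real = nnd_cross(channel_a, channel_b).mean
    params = fit_matern(channel_a, roi)
    rows = []
    for rep in range(n_replicates):
        try:
            sim_a, gof = fitted_simulation(
                channel_a, roi, rng=rng, params=params,
                max_attempts=max_attempts,
            )
        except FittedSimulationError as exc:
            # keep the best (closest) candidate, flagged, rather than
            # dropping the replicate
            if exc.best_pattern is None:
                raise
            sim_a, gof = exc.best_pattern, exc.best
        rows.append(
            {"roi_id": roi.id, "replicate": rep, "real_mean_nnd_ab": real,
             "sim_mean_nnd_ab": nnd_cross(sim_a, channel_b).mean,
             "sim_accepted": gof.accepted}
        )
    return pd.DataFrame(rows)
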