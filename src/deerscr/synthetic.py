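"""Synthetic landscapes, survey designs, populations and noisy genotypes.

Emulates a non-invasive fecal-DNA survey of white-tailed deer on a small
boreal study area: a forest patch (coniferous/mixed/transitional mosaic)
surrounded by agricultural fields, a clustered plot design (23 clusters of
4 plots, ~60 m within and ~300 m between clusters), two closed annual
sessions with 2 and 5 sampling occasions, half-normal detection around
latent activity centers, and a 14-locus microsatellite panel genotyped in
triplicate with amplification failure and allelic dropout.

Every generator takes an explicit :class:`numpy.random.Generator` or seed,
so all outputs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encounters import DetectionRecord
from .genotyping import ReplicateCalls
from .landscape import (
    HABITAT_CODES,
    FeatureSet,
    FineRaster,
    StateSpace,
    TrapArray,
)

__all__ = [
    "LandscapeConfig",
    "DesignConfig",
    "TruthConfig",
    "GenotypingConfig",
    "SimConfig",
    "SimulationTruth",
    "paper_design_config",
    "gen_landscape",
    "gen_design",
    "session_log_intensity",
    "simulate_population",
    "simulate_detections",
    "simulate_genotyping",
]


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class LandscapeConfig:
    """Forest-patch-in-fields landscape at fine (20 m) resolution.

    ``mixture`` is the target class share of the *state space*; the forest
    patch is the trap rectangle expanded by ``forest_margin_m`` and is
    tiled by a seeded Voronoi mosaic of the three forest classes.
    """

    cellsize_m: float = 20.0
    mixture: dict[str, float] = field(default_factory=lambda: {
        "agricultural": 0.76, "coniferous": 0.12, "mixed": 0.06,
        "transitional": 0.06,
    })
    forest_margin_m: float = 200.0
    n_forest_seeds: int = 48
    n_artificial_blobs: int = 6
    water_offset_m: float = 500.0  # vertical stream this far left of the forest


@dataclass
class DesignConfig:
    """Clustered plot design: a cluster grid with one corner cluster
    dropped (23 clusters x 4 plots = 92 plots).

    Row pitch is slightly under the nominal 300 m so that the 1000
    m-buffered bounding rectangle tiles to a 25 x 29 pixel state space at
    120 m, matching the extent of the field study this emulates.
    """

    n_cols: int = 4
    n_rows: int = 6
    drop_clusters: tuple[tuple[int, int], ...] = ((3, 5),)
    between_x_m: float = 300.0
    between_y_m: float = 278.0
    within_m: float = 60.0


@dataclass
class TruthConfig:
    """Generating SCR parameters on the link scales.

    Densities are per pixel (log link); ``density_intercept`` of
    log(16 * 0.0144) puts about 16 deer/km² in the reference class and
    session.  Detection is logit-scale; sigma log-scale meters.
    """

    density_intercept: float = float(np.log(16.0 * 0.0144))
    density_session: dict[str, float] = field(default_factory=lambda: {"2017": 0.88})
    density_habitat: dict[str, float] = field(default_factory=dict)
    p0_intercept: float = -2.08
    p0_session: dict[str, float] = field(default_factory=lambda: {"2017": -1.13})
    p0_sex_male: float = 0.0
    p0_occasion: dict[int, float] = field(default_factory=dict)
    log_sigma: float = float(np.log(270.0))
    log_sigma_male: float = 0.0
    log_sigma_session: dict[str, float] = field(default_factory=dict)
    psi_female: float = 0.5


@dataclass
class GenotypingConfig:
    """Microsatellite panel and per-replicate error process.

    Defaults (f = 0.21 amplification failure, d = 0.18 allelic dropout,
    triplicate PCR, 14 loci with 4 equifrequent alleles) put the >= 11-loci
    pass rate at ~32%, the success rate typical of fecal DNA here.
    """

    n_loci: int = 14
    n_alleles: int = 4
    n_replicates: int = 3
    p_fail: float = 0.21
    p_dropout: float = 0.18
    min_loci: int = 11


@dataclass
class SimConfig:
    seed: int = 0
    sessions: dict[str, int] = field(default_factory=lambda: {"2016": 2, "2017": 5})
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    truth: TruthConfig = field(default_factory=TruthConfig)
    genotyping: GenotypingConfig = field(default_factory=GenotypingConfig)


def paper_design_config(seed: int = 0) -> SimConfig:
    """The ``paper-2016-2017`` scenario: all survey constants at their
    study-design values."""
    return SimConfig(seed=seed)


@dataclass
class SimulationTruth:
    """Ground truth kept for recovery tests."""

    sessions: dict[str, dict]  # session -> {centers (N,2), sex (N,), N}
    config: SimConfig

    def n_total(self) -> int:
        return sum(v["N"] for v in self.sessions.values())


# ---------------------------------------------------------------------------
# Landscape

def gen_design(config: DesignConfig | None = None, origin: tuple[float, float] = (0.0, 0.0)) -> TrapArray:
    """Clustered trap array: 4 plots per cluster on a 60 m square."""
    config = config or DesignConfig()
    if config.between_x_m <= 0 or config.between_y_m <= 0 or config.within_m <= 0:
        raise ValueError("spacings must be positive")
    half = config.within_m / 2.0
    ids, xs, ys = [], [], []
    c = 0
    for row in range(config.n_rows):
        for col in range(config.n_cols):
            if (col, row) in config.drop_clusters:
                continue
            c += 1
            cx = origin[0] + col * config.between_x_m
            cy = origin[1] + row * config.between_y_m
            for p, (dx, dy) in enumerate(
                    [(-half, -half), (half, -half), (-half, half), (half, half)], start=1):
                ids.append(f"C{c:02d}P{p}")
                xs.append(cx + dx)
                ys.append(cy + dy)
    return TrapArray(ids=np.array(ids), x=np.array(xs), y=np.array(ys))


def gen_landscape(traps: TrapArray, config: LandscapeConfig | None = None,
                  buffer_m: float = 1000.0,
                  rng: np.random.Generator | int | None = 0,
                  ) -> tuple[FineRaster, FeatureSet]:
    """Seeded forest-patch landscape plus feature point sets.

    The raster covers the buffered trap rectangle (with one coarse pixel of
    margin).  Forest-class blobs come from a Voronoi partition of random
    seed points inside the forest patch, with seed counts proportional to
    the target within-forest shares; a one-cell-wide stream and a few small
    artificial blobs sit in the surrounding fields.
    """
    config = config or LandscapeConfig()
    rng = np.random.default_rng(rng)
    cs = config.cellsize_m
    margin = 80.0
    xll = float(np.floor((traps.x.min() - buffer_m - margin) / cs) * cs)
    yll = float(np.floor((traps.y.min() - buffer_m - margin) / cs) * cs)
    xur = float(np.ceil((traps.x.max() + buffer_m + margin) / cs) * cs)
    yur = float(np.ceil((traps.y.max() + buffer_m + margin) / cs) * cs)
    ncols = int(round((xur - xll) / cs))
    nrows = int(round((yur - yll) / cs))
    xc = xll + (np.arange(ncols) + 0.5) * cs
    yc = yll + (nrows - np.arange(nrows) - 0.5) * cs
    xx, yy = np.meshgrid(xc, yc)

    values = np.full((nrows, ncols), HABITAT_CODES["agricultural"], dtype=int)

    fx0 = traps.x.min() - config.forest_margin_m
    fx1 = traps.x.max() + config.forest_margin_m
    fy0 = traps.y.min() - config.forest_margin_m
    fy1 = traps.y.max() + config.forest_margin_m
    forest = (xx >= fx0) & (xx <= fx1) & (yy >= fy0) & (yy <= fy1)

    # within-forest shares renormalised from the forest classes of `mixture`
    forest_classes = ("coniferous", "mixed", "transitional")
    shares = np.array([config.mixture[c] for c in forest_classes], dtype=float)
    shares /= shares.sum()
    counts = np.where(shares > 0,
                      np.maximum(1, np.round(shares * config.n_forest_seeds)), 0).astype(int)
    seed_xy, seed_cls = [], []
    for cls, cnt in zip(forest_classes, counts):
        for _ in range(cnt):
            seed_xy.append((rng.uniform(fx0, fx1), rng.uniform(fy0, fy1)))
            seed_cls.append(HABITAT_CODES[cls])
    seed_xy = np.asarray(seed_xy)
    seed_cls = np.asarray(seed_cls)
    fmask = forest.ravel()
    pts = np.column_stack([xx.ravel()[fmask], yy.ravel()[fmask]])
    from scipy.spatial import cKDTree

    _, nearest = cKDTree(seed_xy).query(pts)
    flat = values.ravel()
    flat[fmask] = seed_cls[nearest]
    values = flat.reshape(nrows, ncols)

    # stream: one-cell-wide vertical line in the fields west of the forest
    water_x = fx0 - config.water_offset_m
    col = int(np.argmin(np.abs(xc - water_x)))
    values[:, col] = HABITAT_CODES["water"]

    # a few 2x2 artificial (farmyard) blobs scattered in the fields
    for _ in range(config.n_artificial_blobs):
        for _try in range(100):
            r = rng.integers(1, nrows - 2)
            ccol = rng.integers(1, ncols - 2)
            if (values[r:r + 2, ccol:ccol + 2] == HABITAT_CODES["agricultural"]).all():
                values[r:r + 2, ccol:ccol + 2] = HABITAT_CODES["artificial"]
                break

    raster = FineRaster(xll=xll, yll=yll, cellsize=cs, values=values)
    features = FeatureSet()
    for name in ("water", "artificial", "agricultural"):
        features.add(name, raster.class_points(name))
    return raster, features


# ---------------------------------------------------------------------------
# Population and detections

def session_log_intensity(space: StateSpace, truth: TruthConfig,
                          session: str) -> np.ndarray:
    """Per-pixel log expected count for one session (forward model)."""
    eta = np.full(space.n_pixels, truth.density_intercept, dtype=float)
    eta += truth.density_session.get(session, 0.0)
    if truth.density_habitat:
        if space.habitat is None:
            raise ValueError("habitat contrasts need a classified state space")
        for cls, beta in truth.density_habitat.items():
            eta = eta + np.where(np.asarray(space.habitat) == cls, beta, 0.0)
    return eta


def simulate_population(space: StateSpace, truth: TruthConfig,
                        sessions: list[str],
                        rng: np.random.Generator | int | None = 0) -> SimulationTruth:
    """Poisson population per session; activity centers placed proportional
    to the pixel intensities with uniform jitter inside the pixel."""
    rng = np.random.default_rng(rng)
    half = space.resolution / 2.0
    out: dict[str, dict] = {}
    for g in sessions:
        mu = np.exp(session_log_intensity(space, truth, g))
        N = int(rng.poisson(mu.sum()))
        pix = rng.choice(space.n_pixels, size=N, p=mu / mu.sum())
        cx = space.x[pix] + rng.uniform(-half, half, size=N)
        cy = space.y[pix] + rng.uniform(-half, half, size=N)
        sex = np.where(rng.random(N) < truth.psi_female, "F", "M")
        out[g] = {"centers": np.column_stack([cx, cy]), "sex": sex, "N": N}
    return SimulationTruth(sessions=out, config=None)


def _p0_logit(truth: TruthConfig, session: str, occasion: int, sex: str) -> float:
    eta = truth.p0_intercept
    eta += truth.p0_session.get(session, 0.0)
    eta += truth.p0_occasion.get(occasion, 0.0)
    if sex == "M":
        eta += truth.p0_sex_male
    return eta


def _log_sigma(truth: TruthConfig, session: str, sex: str) -> float:
    eta = truth.log_sigma + truth.log_sigma_session.get(session, 0.0)
    if sex == "M":
        eta += truth.log_sigma_male
    return eta


def simulate_detections(truth_pop: SimulationTruth, traps: TrapArray,
                        sessions: dict[str, int], truth: TruthConfig,
                        rng: np.random.Generator | int | None = 0,
                        ) -> list[DetectionRecord]:
    """Bernoulli half-normal detections; undetected individuals stay only in
    the truth object."""
    from scipy.special import expit

    rng = np.random.default_rng(rng)
    records: list[DetectionRecord] = []
    for g, K in sessions.items():
        pop = truth_pop.sessions[g]
        N = pop["N"]
        if N == 0:
            continue
        d2 = ((pop["centers"][:, 0:1] - traps.x[None, :]) ** 2
              + (pop["centers"][:, 1:2] - traps.y[None, :]) ** 2)
        for sex in ("F", "M"):
            idx = np.nonzero(pop["sex"] == sex)[0]
            if idx.size == 0:
                continue
            sigma = np.exp(_log_sigma(truth, g, sex))
            gd = np.exp(-d2[idx] / (2.0 * sigma * sigma))  # (n, J)
            for k in range(1, K + 1):
                p0 = expit(_p0_logit(truth, g, k, sex))
                hits = rng.random(gd.shape) < p0 * gd
                for ii, jj in zip(*np.nonzero(hits)):
                    records.append(DetectionRecord(
                        individual=f"{g}_ind{idx[ii] + 1:04d}", sex=sex,
                        trap=str(traps.ids[jj]), occasion=k, session=g,
                    ))
    records.sort(key=lambda r: (r.session, r.occasion, r.individual, r.trap))
    return records


# ---------------------------------------------------------------------------
# Genotyping

def simulate_genotyping(records: list[DetectionRecord],
                        config: GenotypingConfig | None = None,
                        rng: np.random.Generator | int | None = 0,
                        ) -> tuple[list[ReplicateCalls], pd.DataFrame]:
    """Turn each detection into a fecal sample with replicated PCR calls.

    True genotypes are drawn once per individual from equifrequent
    ``n_alleles``-allele loci under Hardy-Weinberg; each replicate at each
    locus fails with probability ``p_fail``, else a heterozygote loses a
    random allele with probability ``p_dropout``.  Returns the replicate
    calls plus a sample metadata table (sample, session, trap, occasion,
    true individual, sex).
    """
    config = config or GenotypingConfig()
    if not (0 <= config.p_fail <= 1 and 0 <= config.p_dropout <= 1):
        raise ValueError("error rates must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    loci = [f"L{i + 1:02d}" for i in range(config.n_loci)]
    alleles = [str(100 + 2 * a) for a in range(config.n_alleles)]

    genotypes: dict[str, dict[str, tuple[str, str]]] = {}
    for r in records:
        if r.individual not in genotypes:
            g = {}
            for locus in loci:
                a, b = rng.choice(config.n_alleles, size=2)
                pair = sorted([alleles[a], alleles[b]])
                g[locus] = (pair[0], pair[1])
            genotypes[r.individual] = g

    out: list[ReplicateCalls] = []
    meta_rows = []
    for s_idx, r in enumerate(records, start=1):
        sample = f"S{s_idx:05d}"
        true_g = genotypes[r.individual]
        calls: dict[str, list[tuple[str, str] | None]] = {}
        for locus in loci:
            a, b = true_g[locus]
            reps: list[tuple[str, str] | None] = []
            for _ in range(config.n_replicates):
                if rng.random() < config.p_fail:
                    reps.append(None)
                elif a != b and rng.random() < config.p_dropout:
                    kept = a if rng.random() < 0.5 else b
                    reps.append((kept, kept))
                else:
                    reps.append((a, b))
            calls[locus] = reps
        out.append(ReplicateCalls(sample=sample, calls=calls, session=r.session,
                                  trap=r.trap, occasion=r.occasion))
        meta_rows.append({"sample": sample, "session": r.session, "trap": r.trap,
                          "occasion": r.occasion, "individual": r.individual,
                          "sex": r.sex})
    return out, pd.DataFrame(meta_rows)
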