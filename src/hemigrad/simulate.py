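"""Synthetic multi-site case-control cohorts with planted gradient asymmetries.

The generator emulates the situation the analysis pipeline is built for: a
two-group (HC vs SZ), multi-site resting-state cohort, delivered as
parcellated regional time series, whose regional covariance structure encodes
three latent gradient axes.  Hemispheric asymmetry is planted by shifting the
latent axis loadings of one hemisphere's regions in a chosen network, for the
patient group only, so the full pipeline (FC -> gradients -> asymmetry ->
group statistics) has a known ground truth to recover.

Generative model
----------------
Each region ``i`` carries a 3-vector of latent loadings ``x_i``.  Pairwise
covariance follows a latent-position (Gaussian-kernel) model::

    cov(i, j) = base + exp(-||x_i - x_j||^2 / ell^2)            (+ jitter on i=j)

Diffusion-map embedding of such matrices orders regions along the latent
axes, so the embedding of the resulting FC recovers the loadings up to
rotation and scale.  Homotopic partners share identical loadings for healthy
controls (true asymmetry exactly zero); for patients, the left-hemisphere
loadings of the target network's regions are shifted along the target axis.
One consistent latent point set generates the whole covariance (which keeps
it positive definite), so a planted shift reaches both the intra- and
inter-hemispheric blocks; the effect's ``kind`` records which asymmetry
family the recovery analysis targets.

Site effects follow the ComBat location/scale model.  On raw time series
they are affine per subject (and therefore invisible to Pearson FC — see
:func:`simulate_site_features` for the feature-level site simulation used to
exercise harmonization).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import MAX_SEED, rng_for_subject
from .exceptions import DataError, NumericalError, ParameterError
from .parcellation import CANONICAL_NETWORKS, ParcellationInfo

#: default latent-axis spreads (axis SDs decrease: G1 > G2 > G3)
DEFAULT_SPREADS = (1.0, 0.75, 0.5)
DEFAULT_KERNEL_BASE = 0.1
DEFAULT_LENGTH_SCALE = 0.8
DEFAULT_JITTER = 0.05
#: planted shift magnitude, in units of the target axis loading SD
DEFAULT_EFFECT_MAGNITUDE = 0.5


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """One participant's phenotype row.

    ``effect_scale`` is a latent per-subject multiplier on planted asymmetry
    shifts (1.0 for controls); it is ground truth, not phenotype, and is not
    written to the phenotype CSV.
    """

    subject_id: str
    group: str            # "HC" or "SZ"
    age: float            # years
    sex: str              # "F" or "M"
    site: str
    mean_fd: float        # mm
    max_fd: float         # mm
    panss_pos: float | None = None
    panss_neg: float | None = None
    panss_gen: float | None = None
    effect_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in ("HC", "SZ"):
            raise ParameterError(f"group must be HC or SZ, got {self.group!r}")
        if self.mean_fd < 0:
            raise DataError(f"mean_fd must be >= 0 for {self.subject_id}")
        if self.group == "HC" and any(
            v is not None for v in (self.panss_pos, self.panss_neg, self.panss_gen)
        ):
            raise DataError("PANSS scores are only defined for the SZ group")


@dataclass(frozen=True)
class EffectSpec:
    """A planted asymmetry: (network, gradient axis, intra/inter, magnitude).

    ``magnitude`` is signed and expressed in units of the target axis
    loading SD; positive means leftward asymmetry (left score raised),
    negative rightward.
    """

    network: str
    gradient: int         # 1-based axis index (1..3)
    kind: str             # "intra" or "inter"
    magnitude: float = DEFAULT_EFFECT_MAGNITUDE

    def __post_init__(self) -> None:
        if self.kind not in ("intra", "inter"):
            raise ParameterError(f"effect kind must be intra|inter, got {self.kind!r}")
        if not 1 <= self.gradient <= 3:
            raise ParameterError("effect gradient must be 1, 2 or 3")


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted structure."""

    axis_loadings: np.ndarray                # (n_per_hemi, 3), shared by hemispheres
    effects: tuple[EffectSpec, ...]          # applied to SZ subjects only
    site_location: dict[str, float]
    site_scale: dict[str, float]
    subject_effect_scale: dict[str, float] = field(default_factory=dict)
    kernel_base: float = DEFAULT_KERNEL_BASE
    length_scale: float = DEFAULT_LENGTH_SCALE
    jitter: float = DEFAULT_JITTER

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.site_scale.values()):
            raise ParameterError("site_scale values must be > 0")

    @property
    def effect_map(self) -> list[tuple[str, int, str, str]]:
        """(network, gradient, kind, direction) expected to reach significance."""
        return [
            (e.network, e.gradient, e.kind, "leftward" if e.magnitude > 0 else "rightward")
            for e in self.effects
        ]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["axis_loadings"] = self.axis_loadings.tolist()
        d["effects"] = [dataclasses.asdict(e) for e in self.effects]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["axis_loadings"] = np.asarray(d["axis_loadings"], dtype=float)
        d["effects"] = tuple(EffectSpec(**e) for e in d["effects"])
        return cls(**d)


# ---------------------------------------------------------------------------
# parcellation generator
# ---------------------------------------------------------------------------

def generate_parcellation(
    n_per_hemi: int = 200, n_networks: int = 7, seed: int = 0
) -> ParcellationInfo:
    """Build a homotopic parcellation with L-first ordering.

    Regions 0..n-1 are left hemisphere, n..2n-1 right; partner(i) = i + n.
    Networks are contiguous, near-equal blocks of within-hemisphere index,
    mirrored across hemispheres.  ``seed`` is accepted for interface symmetry;
    the construction is deterministic.
    """
    del seed  # construction is deterministic
    if n_per_hemi < 8:
        raise ParameterError(f"n_per_hemi must be >= 8, got {n_per_hemi}")
    if not 1 <= n_networks <= n_per_hemi:
        raise ParameterError("need 1 <= n_networks <= n_per_hemi")
    labels = list(CANONICAL_NETWORKS[:n_networks])
    labels += [f"NET{i}" for i in range(8, n_networks + 1)]
    bounds = np.linspace(0, n_per_hemi, n_networks + 1).round().astype(int)
    net_per_region = np.empty(n_per_hemi, dtype=object)
    for k in range(n_networks):
        net_per_region[bounds[k]:bounds[k + 1]] = labels[k]
    n = 2 * n_per_hemi
    return ParcellationInfo(
        region_id=np.arange(n),
        hemisphere=np.array(["L"] * n_per_hemi + ["R"] * n_per_hemi, dtype=object),
        partner_id=np.concatenate(
            [np.arange(n_per_hemi) + n_per_hemi, np.arange(n_per_hemi)]
        ),
        network=np.concatenate([net_per_region, net_per_region]),
    )


# ---------------------------------------------------------------------------
# latent loadings and ground truth
# ---------------------------------------------------------------------------

def latent_loadings(
    n_per_hemi: int, spreads: tuple[float, float, float] = DEFAULT_SPREADS
) -> np.ndarray:
    """Deterministic 3-axis latent positions for one hemisphere.

    The axes are smooth, mutually orthogonal functions of the region index
    (linear, second harmonic, third harmonic) scaled to the requested SDs,
    mirroring how empirical connectome gradients are smooth spatial maps of
    decreasing variance.  Smoothness is what makes the axes recoverable by
    diffusion embedding even for small parcellations, and makes a network's
    embedded response to a planted shift spatially coherent.
    """
    t = np.linspace(0.0, 1.0, n_per_hemi)
    X = np.column_stack(
        [2 * t - 1, np.cos(2 * np.pi * t), np.cos(3 * np.pi * t)]
    )
    return X / X.std(axis=0) * np.asarray(spreads, dtype=float)


def generate_truth(
    parcellation: ParcellationInfo,
    effects: tuple[EffectSpec, ...] | list[EffectSpec] = (),
    n_sites: int = 1,
    seed: int = 0,
    spreads: tuple[float, float, float] = DEFAULT_SPREADS,
    site_location_sd: float = 0.5,
    site_scale_sd: float = 0.15,
    **kernel_params,
) -> GroundTruth:
    """Draw site effects and assemble the ground truth for a study."""
    known = set(parcellation.networks)
    for e in effects:
        if e.network not in known:
            raise ParameterError(f"effect network {e.network!r} not in parcellation")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & MAX_SEED, 17]))
    sites = [f"site{i + 1}" for i in range(n_sites)]
    return GroundTruth(
        axis_loadings=latent_loadings(len(parcellation.left_indices), spreads),
        effects=tuple(effects),
        site_location={s: float(rng.normal(0.0, site_location_sd)) for s in sites},
        site_scale={s: float(np.exp(rng.normal(0.0, site_scale_sd))) for s in sites},
        **kernel_params,
    )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def generate_cohort(
    n_hc: int,
    n_sz: int,
    n_sites: int,
    seed: int,
    female_fraction: float = 0.33,
    effects: tuple[EffectSpec, ...] | list[EffectSpec] = (),
    effect_scale_sd: float = 0.4,
    panss_beta: float = 2.0,
    panss_noise_sd: float = 4.0,
) -> list[SubjectRecord]:
    """Generate phenotype records for a two-group multi-site cohort.

    Ages ~ Normal(36, 11) truncated to [18, 65]; sex ~ Bernoulli(female
    fraction); mean FD ~ lognormal calibrated so defaults rarely exceed
    0.35 mm (patients fractionally higher, as in typical cohorts).  SZ
    subjects receive a latent effect-scale multiplier ~ Normal(1, sd)
    truncated at 0.1, and PANSS-positive scores linear in that multiplier
    (signal-to-noise set by ``panss_beta`` / ``panss_noise_sd``; the defaults
    give R^2 ~= 0.2 when effects are planted).  Negative and general scores
    are noise, emulating scales the planted asymmetry does not drive.
    """
    if min(n_hc, n_sz, n_sites) < 1:
        raise ParameterError("all counts must be >= 1")
    if n_sites > n_hc + n_sz:
        raise ParameterError("more sites than subjects")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & MAX_SEED, 29]))
    sites = [f"site{i + 1}" for i in range(n_sites)]
    total_mag = float(sum(abs(e.magnitude) for e in effects))
    records: list[SubjectRecord] = []
    counter = 0
    for group, count in (("HC", n_hc), ("SZ", n_sz)):
        for k in range(count):
            counter += 1
            sid = f"sub-{counter:04d}"
            age = float(np.clip(rng.normal(36.0, 11.0), 18.0, 65.0))
            sex = "F" if rng.random() < female_fraction else "M"
            fd_mu = np.log(0.16 if group == "SZ" else 0.15)
            mean_fd = float(np.exp(rng.normal(fd_mu, 0.35)))
            max_fd = float(mean_fd * rng.uniform(3.0, 10.0))
            rec = SubjectRecord(
                subject_id=sid, group=group, age=age, sex=sex,
                site=sites[k % n_sites], mean_fd=mean_fd, max_fd=max_fd,
            )
            if group == "SZ":
                e_scale = float(max(0.1, rng.normal(1.0, effect_scale_sd)))
                rec.effect_scale = e_scale
                signal = (e_scale - 1.0) / max(effect_scale_sd, 1e-12)
                rec.panss_pos = _panss(15.0 + panss_beta * signal * (total_mag > 0)
                                       + rng.normal(0.0, panss_noise_sd), rng)
                rec.panss_neg = _panss(15.0 + rng.normal(0.0, panss_noise_sd), rng)
                rec.panss_gen = _panss(30.0 + 0.8 * signal * (total_mag > 0)
                                       + rng.normal(0.0, 1.5 * panss_noise_sd), rng)
            records.append(rec)
    return records


def _panss(value: float, rng: np.random.Generator) -> float:
    del rng
    return float(np.clip(round(value), 7, 112))


# ---------------------------------------------------------------------------
# covariance and time series
# ---------------------------------------------------------------------------

def _kernel(X: np.ndarray, Y: np.ndarray, base: float, ell: float) -> np.ndarray:
    d2 = ((X[:, None, :] - Y[None, :, :]) ** 2).sum(-1)
    return base + np.exp(-d2 / ell**2)


def _shifted_loadings(
    base: np.ndarray, parcellation: ParcellationInfo, effects, scale: float,
) -> np.ndarray:
    """Apply the planted shifts to the left hemisphere's loadings.

    Shifts are carried entirely by the left hemisphere: a positive
    (leftward) magnitude raises the left loadings on the target axis, a
    negative one lowers them; the right hemisphere keeps the base geometry.
    A single latent geometry generates the whole covariance (that is what
    keeps it positive definite), so a planted shift propagates to both the
    intra- and inter-hemispheric blocks; the effect's ``kind`` records which
    AI family the recovery analysis targets.
    """
    X = base.copy()
    sd = base.std(axis=0)
    hemi_networks = parcellation.network[parcellation.left_indices]
    for e in effects:
        mask = hemi_networks == e.network
        g = e.gradient - 1
        X[mask, g] += scale * e.magnitude * sd[g]
    return X


def build_truth_covariance(
    parcellation: ParcellationInfo,
    subject: SubjectRecord,
    truth: GroundTruth,
) -> np.ndarray:
    """Region x region covariance encoding the subject's latent geometry.

    HC subjects get hemispherically symmetric covariance (expected AI = 0);
    SZ subjects get the planted shifts scaled by their latent effect scale,
    applied to the left-hemisphere latent positions.  The full covariance is
    the Gaussian kernel over one consistent latent point set plus ``jitter``
    on the diagonal, and must pass a Cholesky positive-definiteness check.
    """
    X0 = truth.axis_loadings
    if not np.all(np.isfinite(X0)):
        raise DataError("axis loadings must be finite")
    nh = X0.shape[0]
    if 2 * nh != parcellation.n_regions:
        raise DataError("loadings do not match parcellation size")
    effects = truth.effects if subject.group == "SZ" else ()
    scale = subject.effect_scale if subject.group == "SZ" else 0.0
    base, ell = truth.kernel_base, truth.length_scale

    X_left = _shifted_loadings(X0, parcellation, effects, scale)
    X_all = np.empty((parcellation.n_regions, X0.shape[1]))
    X_all[parcellation.left_indices] = X_left
    X_all[parcellation.right_indices] = X0
    n = 2 * nh
    cov = _kernel(X_all, X_all, base, ell)
    cov = 0.5 * (cov + cov.T) + truth.jitter * np.eye(n)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        lam_min = float(np.linalg.eigvalsh(cov).min())
        raise NumericalError(
            "assembled covariance is not positive definite after jitter "
            f"{truth.jitter} (min eigenvalue {lam_min:.3e}); increase jitter "
            "or reduce planted shift magnitudes"
        ) from None
    return cov


def sample_timeseries(
    covariance: np.ndarray,
    n_timepoints: int,
    subject: SubjectRecord,
    truth: GroundTruth,
    seed: int,
) -> np.ndarray:
    """Draw a (regions x timepoints) series from N(0, covariance).

    The subject's site location (additive) and scale (multiplicative)
    effects are applied afterwards.  The random stream is derived from
    (seed, subject_id), so cohorts are reproducible subject-by-subject.
    """
    n = covariance.shape[0]
    if n_timepoints < 2 * n:
        warnings.warn(
            f"n_timepoints={n_timepoints} < 2 x n_regions={2 * n}; "
            "sample FC will be very noisy", stacklevel=2,
        )
    try:
        L = np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError:
        raise NumericalError("covariance is singular or not PD") from None
    rng = rng_for_subject(seed, subject.subject_id)
    ts = L @ rng.standard_normal((n, n_timepoints))
    loc = truth.site_location.get(subject.site, 0.0)
    scl = truth.site_scale.get(subject.site, 1.0)
    return scl * ts + loc


# ---------------------------------------------------------------------------
# study-level convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    parcellation: ParcellationInfo
    subjects: list[SubjectRecord]
    truth: GroundTruth
    timeseries: dict[str, np.ndarray]
    seed: int

    @property
    def phenotype(self) -> pd.DataFrame:
        return subjects_to_frame(self.subjects)


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    cols = ["subject_id", "group", "age", "sex", "site", "mean_fd", "max_fd",
            "panss_pos", "panss_neg", "panss_gen"]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in subjects])


def simulate_study(
    n_hc: int = 40,
    n_sz: int = 40,
    n_sites: int = 2,
    n_per_hemi: int = 32,
    n_networks: int = 7,
    n_timepoints: int = 300,
    effects: tuple[EffectSpec, ...] | list[EffectSpec] = (),
    seed: int = 0,
    **kwargs,
) -> SimulatedStudy:
    """Generate a complete synthetic study (parcellation, phenotype, series)."""
    parcellation = generate_parcellation(n_per_hemi, n_networks, seed)
    truth = generate_truth(parcellation, effects, n_sites, seed,
                           **{k: v for k, v in kwargs.items()
                              if k in ("spreads", "site_location_sd", "site_scale_sd",
                                       "kernel_base", "length_scale", "jitter")})
    cohort_kw = {k: v for k, v in kwargs.items()
                 if k in ("female_fraction", "effect_scale_sd",
                          "panss_beta", "panss_noise_sd")}
    subjects = generate_cohort(n_hc, n_sz, n_sites, seed, effects=effects, **cohort_kw)
    truth.subject_effect_scale = {s.subject_id: s.effect_scale for s in subjects}
    series: dict[str, np.ndarray] = {}
    for s in subjects:
        cov = build_truth_covariance(parcellation, s, truth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series[s.subject_id] = sample_timeseries(cov, n_timepoints, s, truth, seed)
    return SimulatedStudy(parcellation, subjects, truth, series, seed)


# ---------------------------------------------------------------------------
# feature-level site simulation (ComBat generative model)
# ---------------------------------------------------------------------------

def simulate_site_features(
    n_per_site: int = 40,
    n_sites: int = 2,
    n_features: int = 10,
    group_effect: float = 0.5,
    n_group_features: int = 3,
    site_location_sd: float = 0.6,
    site_scale_sd: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, dict]:
    """Subject x feature matrix under the ComBat location/scale model.

    y_ijf = alpha_f + group_i * beta_f + gamma_(site)f + delta_(site)f * eps;
    groups are balanced within sites (site orthogonal to group), so planted
    group effects should survive harmonization.  Returns (features, site
    labels, phenotype frame, truth dict with the planted gammas/deltas).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & MAX_SEED, 41]))
    n = n_per_site * n_sites
    site = np.repeat([f"site{i + 1}" for i in range(n_sites)], n_per_site)
    group = np.tile(
        np.array(["HC", "SZ"])[np.arange(n_per_site) % 2], n_sites
    )
    alpha = rng.normal(0.0, 1.0, n_features)
    beta = np.zeros(n_features)
    beta[:n_group_features] = group_effect
    gamma = rng.normal(0.0, site_location_sd, (n_sites, n_features))
    delta = np.exp(rng.normal(0.0, site_scale_sd, (n_sites, n_features)))
    site_idx = np.repeat(np.arange(n_sites), n_per_site)
    eps = rng.standard_normal((n, n_features))
    y = (alpha + (group == "SZ")[:, None] * beta
         + gamma[site_idx] + delta[site_idx] * eps)
    pheno = pd.DataFrame({
        "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
        "group": group, "site": site,
        "age": rng.normal(36, 11, n).clip(18, 65),
        "sex": np.where(rng.random(n) < 0.33, "F", "M"),
        "mean_fd": np.exp(rng.normal(np.log(0.15), 0.35, n)),
    })
    return y, site, pheno, {"alpha": alpha, "beta": beta, "gamma": gamma, "delta": delta}
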