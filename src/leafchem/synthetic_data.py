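"""Synthetic leaf study generator with known ground truth.

Emulates a two-experiment nitrogen-response study on fresh maize leaves:
a panel of 24 free amino acids measured per leaf (umol/L) together with the
leaf's mean reflectance spectrum on a 400-1000 nm grid. The generator is the
test bed for the whole pipeline — every planted quantity (which wavelengths
carry analyte signal, how strongly each analyte couples to the spectrum, the
true leaf mask inside an image cube) is returned, so recovery can be checked
exactly.

Model
-----
Concentrations are drawn log-normally, moment-matched per analyte to a
reference panel of descriptive statistics typical of fresh maize leaves
under varied nitrogen supply (positive, strongly right-skewed analytes).
Reflectance is a smooth leaf baseline (green peak, red edge, NIR plateau)
perturbed by Gaussian absorption features whose depths are a bounded
monotone map of standardized concentrations through an analyte x feature
coupling matrix:

    r_i = clip( g_i * ( baseline - sum_f d(z_i . C_f) * N(lambda; c_f, s_f) )
                + eps_i , 0, 1 )

with per-sample gain ``g_i = 1 + N(0, multiplicative_sd)``, additive noise
``eps ~ N(0, noise_sd)`` per band, and a bounded monotone depth response
``d(u) = depth_scale * (expit(slope * u) - 1/2)`` (so zero coupling
reproduces the baseline exactly). Feature centers sit in
the green-yellow (505-605 nm) and red/red-edge (651-714 nm) windows where
pigment-driven variation concentrates in real leaves; the NIR plateau is
deliberately quiet, so per-band variability is visibly larger below ~717 nm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .exceptions import ConfigurationError, DegenerateOpticsError
from .tables import SampleTable, wavelength_column

__all__ = [
    "REFERENCE_PANEL",
    "AnalytePanelConfig",
    "OpticsConfig",
    "StudyConfig",
    "default_baseline",
    "default_coupling",
    "generate_concentrations",
    "generate_reflectance",
    "generate_cube",
    "generate_study",
]

# Reference descriptive statistics (umol/L) for 24 free amino acids in fresh
# maize leaves across nitrogen treatments: max, min, mean, SD, CV%.
_REFERENCE_PANEL_CSV = """\
analyte,max,min,mean,sd,cv_percent
Ala,770.64,3.75,145.37,126.77,87.21
GABA,51.17,0.06,10.00,8.06,80.60
BABA,64.08,0.06,7.00,6.60,94.29
Arg,19.55,2.98,7.94,3.73,46.98
Asp,207.79,4.27,41.14,28.85,70.13
Cit,16.51,0.04,4.91,3.85,78.41
Glu,678.80,3.25,166.38,113.28,68.09
Gly,520.43,3.48,35.23,51.36,145.78
His,34.40,0.39,6.49,4.56,70.26
Ile,66.41,0.06,8.16,7.41,90.81
Leu,72.26,2.23,12.92,8.71,67.41
Lys,101.42,0.99,13.80,7.22,52.32
Met,10.55,0.03,4.20,3.05,72.62
Orn,11.24,0.49,5.55,4.40,79.28
Phe,48.76,2.11,9.87,5.10,51.67
Pro,52.69,1.06,10.14,6.82,67.26
Sar,788.29,3.75,149.96,134.36,89.60
Ser,622.39,1.55,63.71,87.94,138.03
Thr,131.36,0.88,21.71,15.35,70.70
Trp,51.27,1.30,8.69,6.90,79.40
Tyr,40.10,2.46,9.86,5.97,60.55
Gln,224.48,0.09,20.93,31.58,150.88
Val,112.95,4.29,19.28,13.27,68.83
Asn,167.89,0.03,13.11,20.83,158.89
"""

REFERENCE_PANEL: pd.DataFrame = pd.read_csv(io.StringIO(_REFERENCE_PANEL_CSV))

# Analytes whose spectral coupling is made strong by default, in descending
# strength order, followed by a medium tier; the rest receive graded weak
# couplings. Strong + medium together fill a complete orthogonal design in
# feature space, so every planted feature carries signal that a model for a
# strong analyte must resolve.
STRONG_ANALYTES = ("BABA", "Orn", "Cit", "Met", "His")
MEDIUM_ANALYTES = ("Sar", "Ala", "Glu")


@dataclass(frozen=True)
class AnalytePanelConfig:
    """Target moments for the analyte concentration panel (umol/L)."""

    names: tuple
    mean: np.ndarray
    sd: np.ndarray
    min_clip: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        n = len(self.names)
        if self.mean.shape != (n,) or self.sd.shape != (n,):
            raise ConfigurationError("panel names/mean/sd lengths disagree")
        if np.any(self.mean <= 0):
            raise ConfigurationError("panel means must be positive")
        if np.any(self.sd < 0) or self.min_clip < 0:
            raise ConfigurationError("panel sd and min_clip must be non-negative")

    @classmethod
    def default(cls) -> "AnalytePanelConfig":
        """The 24-analyte maize-leaf panel."""
        return cls(
            names=tuple(REFERENCE_PANEL["analyte"]),
            mean=REFERENCE_PANEL["mean"].to_numpy(),
            sd=REFERENCE_PANEL["sd"].to_numpy(),
        )


def default_baseline(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth leaf-like reflectance baseline on an arbitrary grid.

    Low visible reflectance with a green peak near 550 nm, a sigmoid red
    edge centered at 720 nm, and an NIR plateau near 0.40.
    """
    wl = np.asarray(wavelengths, dtype=float)
    green = 0.08 * np.exp(-((wl - 550.0) ** 2) / (2 * 30.0**2))
    red_edge = 0.35 * expit((wl - 720.0) / 18.0)
    return 0.05 + green + red_edge


# Default absorption-feature centers (nm): five in the green-yellow window,
# three in the red/red-edge window. Centers are well separated (>= 20 nm)
# relative to the feature width (sigma = 5 nm), so each center's band
# carries signal no neighboring band can substitute.
DEFAULT_SIGNATURE_CENTERS = (512.0, 532.0, 552.0, 573.0, 603.0, 664.0, 685.0, 705.0)
DEFAULT_SIGNATURE_WIDTH = 5.0


def default_coupling(names=None, n_features: int = len(DEFAULT_SIGNATURE_CENTERS)) -> np.ndarray:
    """Deterministic analyte x feature coupling matrix.

    Strong (``STRONG_ANALYTES``) and medium (``MEDIUM_ANALYTES``) analytes
    occupy mutually orthogonal Hadamard loading patterns spanning the whole
    feature space, so each is linearly identifiable and well recoverable
    from the spectrum. The remaining analytes receive dense random
    directions on a graded geometric strength ladder, giving the panel a
    smooth ordering of spectral recoverability.
    """
    if names is None:
        names = tuple(REFERENCE_PANEL["analyte"])
    names = list(names)
    rng = np.random.default_rng(987654321)  # fixed: the coupling is a constant
    coupling = np.zeros((len(names), n_features))
    tiered = list(zip(STRONG_ANALYTES, (2.0, 1.7, 1.5, 1.3, 1.15))) + list(
        zip(MEDIUM_ANALYTES, (1.0, 0.9, 0.8))
    )
    tier_strength = dict(tiered)
    tier_row = {name: k for k, (name, _) in enumerate(tiered)}
    # strong and medium analytes get mutually orthogonal, equal-magnitude
    # mixed-sign loading patterns (Hadamard rows): each is linearly
    # identifiable, its signal reaches every planted wavelength with the
    # same weight, and together they span the whole feature space, so a
    # model for one of them genuinely needs every feature to separate it
    # from the others
    from scipy.linalg import hadamard

    n_had = 1 << (max(n_features, 2) - 1).bit_length()
    basis = hadamard(n_had).astype(float)
    basis = np.vstack([basis[1:], basis[:1]])[:, :n_features]  # all-ones row last
    n_weak = sum(1 for n in names if n not in tier_strength)
    # weak rows come from a random matrix with orthonormalized columns, so
    # their aggregate interference is near-isotropic in feature space (no
    # direction — in particular no tiered analyte's — is hit much harder
    # than another), then each row is scaled onto a graded geometric
    # strength ladder from 0.60 down to 0.12
    weak_dirs, _ = np.linalg.qr(rng.standard_normal((max(n_weak, n_features), n_features)))
    weak_rank = 0
    for i, name in enumerate(names):
        if name in tier_strength:
            row = basis[tier_row[name] % n_had]
            coupling[i] = row / np.linalg.norm(row) * tier_strength[name]
        else:
            strength = 0.60 * (0.12 / 0.60) ** (weak_rank / max(n_weak - 1, 1))
            row = weak_dirs[weak_rank % weak_dirs.shape[0]]
            coupling[i] = row / np.linalg.norm(row) * strength
            weak_rank += 1
    return coupling


@dataclass(frozen=True)
class OpticsConfig:
    """Forward model linking concentrations to leaf reflectance.

    ``baseline_spectrum=None`` means "build :func:`default_baseline` on the
    study grid at generation time"; pass an explicit per-band array to
    override. ``coupling`` rows follow the panel's analyte order.
    """

    signature_centers: tuple = DEFAULT_SIGNATURE_CENTERS
    signature_widths: tuple = tuple([DEFAULT_SIGNATURE_WIDTH] * len(DEFAULT_SIGNATURE_CENTERS))
    coupling: np.ndarray | None = None  # None -> default_coupling at use time
    baseline_spectrum: np.ndarray | None = None
    depth_scale: float = 0.09
    response_slope: float = 0.4
    noise_sd: float = 0.001
    multiplicative_sd: float = 0.005

    def __post_init__(self):
        object.__setattr__(self, "signature_centers", tuple(float(c) for c in self.signature_centers))
        object.__setattr__(self, "signature_widths", tuple(float(w) for w in self.signature_widths))
        if len(self.signature_widths) != len(self.signature_centers):
            raise ConfigurationError("one width per signature center required")
        if any(w <= 0 for w in self.signature_widths):
            raise ConfigurationError("signature widths must be positive")
        if self.noise_sd < 0 or self.multiplicative_sd < 0 or self.depth_scale < 0:
            raise ConfigurationError("noise levels and depth_scale must be non-negative")
        if self.response_slope <= 0:
            raise ConfigurationError("response_slope must be positive")
        if self.baseline_spectrum is not None:
            base = np.asarray(self.baseline_spectrum, dtype=float)
            if np.any(base < 0) or np.any(base > 1):
                raise ConfigurationError("baseline reflectance must lie in [0, 1]")
            object.__setattr__(self, "baseline_spectrum", base)
        if self.coupling is not None:
            object.__setattr__(self, "coupling", np.asarray(self.coupling, dtype=float))

    def resolved_coupling(self, n_analytes: int) -> np.ndarray:
        c = self.coupling if self.coupling is not None else default_coupling()
        if c.shape != (n_analytes, len(self.signature_centers)):
            raise ConfigurationError(
                f"coupling shape {c.shape} != ({n_analytes}, {len(self.signature_centers)})"
            )
        return c


@dataclass(frozen=True)
class StudyConfig:
    """Sample sizes and spectral grid of the emulated two-experiment study."""

    n_exp1: int = 144
    n_exp2: int = 146
    n_bands: int = 300
    wl_min: float = 400.0
    wl_max: float = 1000.0
    cube_shape: tuple = (64, 64)
    seed: int = 0

    def __post_init__(self):
        if self.n_exp1 + self.n_exp2 < 10:
            raise ConfigurationError("need at least 10 samples in total")
        if self.n_bands < 10:
            raise ConfigurationError("need at least 10 bands")
        if not self.wl_min < self.wl_max:
            raise ConfigurationError("wl_min must be below wl_max")

    @property
    def n_samples(self) -> int:
        return self.n_exp1 + self.n_exp2

    def wavelength_grid(self) -> np.ndarray:
        return np.linspace(self.wl_min, self.wl_max, self.n_bands)


def generate_concentrations(n: int, panel: AnalytePanelConfig, seed: int) -> pd.DataFrame:
    """Sample an n x len(panel) concentration table (umol/L).

    Each analyte follows a log-normal law moment-matched to the panel's
    target mean and SD, truncated below at ``min_clip``. Columns are drawn
    as a midpoint quantile sample of that law (inverse CDF at the n
    equal-probability stratum midpoints), independently shuffled per
    column: marginal shape and cross-column independence are those of
    log-normal sampling, while sample means and SDs track the targets far
    more tightly than iid draws would for these heavy-tailed analytes.
    Zero-SD analytes are constant at their mean.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = (np.arange(n) + 0.5) / n
    out = np.empty((n, len(panel.names)))
    for j, (m, s) in enumerate(zip(panel.mean, panel.sd)):
        if s == 0:
            out[:, j] = m
            continue
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        col = stats.lognorm.ppf(u, s=np.sqrt(sigma2), scale=np.exp(mu))
        rng.shuffle(col)
        out[:, j] = col
    np.maximum(out, panel.min_clip, out=out)
    return pd.DataFrame(out, columns=list(panel.names))


def _feature_profiles(optics: OpticsConfig, wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    centers = np.asarray(optics.signature_centers)[:, None]
    widths = np.asarray(optics.signature_widths)[:, None]
    return np.exp(-((wl[None, :] - centers) ** 2) / (2 * widths**2))


def _standardize_columns(conc: np.ndarray) -> np.ndarray:
    mean = conc.mean(axis=0)
    sd = conc.std(axis=0, ddof=1) if conc.shape[0] > 1 else np.zeros(conc.shape[1])
    z = np.zeros_like(conc, dtype=float)
    ok = sd > 0
    z[:, ok] = (conc[:, ok] - mean[ok]) / sd[ok]
    return z


def generate_reflectance(
    concentrations: pd.DataFrame,
    optics: OpticsConfig,
    wavelengths: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Forward-model n leaf spectra from a concentration table."""
    wl = np.asarray(wavelengths, dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ConfigurationError("wavelength grid must be strictly ascending")
    conc = np.asarray(concentrations, dtype=float)
    n = conc.shape[0]
    coupling = optics.resolved_coupling(conc.shape[1])
    baseline = (
        optics.baseline_spectrum
        if optics.baseline_spectrum is not None
        else default_baseline(wl)
    )
    if baseline.shape != wl.shape:
        raise ConfigurationError("baseline length must match the wavelength grid")

    z = _standardize_columns(conc)
    u = z @ coupling                                   # n x features
    # bounded monotone depth response with d(0) = 0; the slope keeps the
    # map near-linear over the bulk of the standardized concentration range
    depth = optics.depth_scale * (expit(optics.response_slope * u) - 0.5)
    profiles = _feature_profiles(optics, wl)           # features x bands

    rng = np.random.default_rng(seed)
    gain = 1.0 + optics.multiplicative_sd * rng.standard_normal(n)
    spectra = gain[:, None] * (baseline[None, :] - depth @ profiles)
    if optics.noise_sd > 0:
        spectra = spectra + optics.noise_sd * rng.standard_normal(spectra.shape)
    clipped = np.clip(spectra, 0.0, 1.0)
    fully_clipped = np.all((spectra <= 0.0) | (spectra >= 1.0), axis=1)
    if np.any(fully_clipped):
        raise DegenerateOpticsError(
            f"{int(fully_clipped.sum())} spectra entirely clipped; "
            "reduce depth_scale or coupling magnitudes"
        )
    return clipped


def background_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Background (stage) reflectance: strictly decreasing in wavelength.

    Decreasing reflectance guarantees NDVI < 0 off-leaf, so NDVI > 0
    segmentation recovers the planted mask without threshold flakiness.
    """
    wl = np.asarray(wavelengths, dtype=float)
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    return 0.30 - 0.25 * t


def generate_cube(
    spectrum: np.ndarray,
    wavelengths: np.ndarray,
    shape: tuple = (64, 64),
    noise_sd: float = 0.002,
    seed: int = 0,
):
    """Render one leaf spectrum into an image cube with a known leaf mask.

    An elliptical "leaf" carries ``spectrum`` plus per-pixel Gaussian noise;
    the background carries :func:`background_spectrum`. Returns
    ``(HyperspectralCube, mask)`` where ``mask`` is the ground-truth boolean
    leaf region.
    """
    from .imaging import HyperspectralCube  # local import to avoid a cycle

    rows, cols = shape
    if rows < 8 or cols < 8:
        raise ConfigurationError("cube shape must be at least (8, 8)")
    spectrum = np.asarray(spectrum, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    if spectrum.shape != wl.shape:
        raise ConfigurationError("spectrum length must match the wavelength grid")

    rr, cc = np.mgrid[0:rows, 0:cols]
    mask = (
        ((rr - (rows - 1) / 2.0) / (0.38 * rows)) ** 2
        + ((cc - (cols - 1) / 2.0) / (0.30 * cols)) ** 2
    ) <= 1.0

    cube = np.empty((rows, cols, len(wl)))
    cube[:, :] = background_spectrum(wl)
    cube[mask] = spectrum
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cube = cube + noise_sd * rng.standard_normal(cube.shape)
    cube = np.clip(cube, 0.0, 1.0)
    return HyperspectralCube(cube, wl), mask


def generate_study(
    study: StudyConfig,
    panel: AnalytePanelConfig | None = None,
    optics: OpticsConfig | None = None,
) -> SampleTable:
    """Generate the full two-experiment sample table.

    Both experiments share one concentration distribution and one forward
    model; the experiment label is metadata only. Reproducible: the study
    seed is split into independent child streams for concentrations and
    reflectance, so the same ``StudyConfig`` always yields the same table.
    """
    panel = panel or AnalytePanelConfig.default()
    optics = optics or OpticsConfig()
    n = study.n_samples
    wl = study.wavelength_grid()

    children = np.random.SeedSequence(study.seed).spawn(2)
    conc_seed = int(children[0].generate_state(1)[0] % (2**31))
    refl_seed = int(children[1].generate_state(1)[0] % (2**31))

    conc = generate_concentrations(n, panel, conc_seed)
    spectra = generate_reflectance(conc, optics, wl, refl_seed)

    frame = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n)],
            "experiment": [1] * study.n_exp1 + [2] * study.n_exp2,
        }
    )
    frame = pd.concat(
        [
            frame,
            conc.reset_index(drop=True),
            pd.DataFrame(spectra, columns=[wavelength_column(w) for w in wl]),
        ],
        axis=1,
    )
    return SampleTable(frame, list(panel.names), wl)


def coupling_strengths(optics: OpticsConfig | None = None, n_analytes: int = 24) -> np.ndarray:
    """Per-analyte spectral coupling strength (row L2 norm), the generator's
    ground-truth ordering of recoverability."""
    optics = optics or OpticsConfig()
    return np.linalg.norm(optics.resolved_coupling(n_analytes), axis=1)
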