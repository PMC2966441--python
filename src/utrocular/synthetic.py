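"""Forward simulation of eye-biased voxel data from a columnar cortical sheet.

The generator builds a flattened patch of early visual cortex carrying an
ocular dominance (OD) map — alternating bands of left/right eye preference
with a period of about 1.6 mm (two ~0.8 mm columns) — and a spatial-frequency
preference map that can be coupled to it, so that low-spatial-frequency
domains sit preferentially at OD column centers.  Stimulating one eye with a
grating then produces a response field whose fine structure follows the OD
map; sampling that field with millimetre-scale voxels leaves each voxel with
a small, stable eye bias (biased sampling of the columnar architecture),
which is exactly the signal the downstream pattern classifier exploits.

The same module simulates block-design BOLD runs from those voxel responses
(HRF-shaped regressors plus AR(1) Gaussian noise) and the out-of-scanner
utrocular-discrimination session (an equal-variance signal-detection
observer with per-spatial-frequency d' and criterion and the constrained
trial ordering used in the task).

Everything is seeded and bit-reproducible: the same configuration and seed
always produce the same dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, signal

from .behavior import BehavioralSession
from .samples import CONDITIONS, EYES, FIXATION, RunData, SFS, condition_label

# Stimulus spatial frequencies on the [0, 1] preference axis: the low
# (0.5 cpd) grating maps to the bottom of the axis, the high (3.6 cpd)
# grating to the top.
SF_AXIS: dict[str, float] = {"low": 0.0, "high": 1.0}


# --------------------------------------------------------------------------
# Experiment design
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentDesign:
    """Block design of one scanning session.

    Defaults mirror a 12-run session in which each run shows each of the
    four conditions (eye x spatial frequency) once for 19.2 s, interleaved
    with 19.2 s fixation, sampled at TR = 3.2 s.
    """

    n_runs: int = 12
    conditions: tuple[str, ...] = CONDITIONS
    block_duration_s: float = 19.2
    fixation_duration_s: float = 19.2
    tr_s: float = 3.2
    order_policy: str = "pseudo-random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        ratio = self.block_duration_s / self.tr_s
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("block_duration_s must be a positive multiple of tr_s")
        fratio = self.fixation_duration_s / self.tr_s
        if abs(fratio - round(fratio)) > 1e-9:
            raise ValueError("fixation_duration_s must be a multiple of tr_s")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be unique (each occurs once per run)")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition token {c!r}")

    @property
    def volumes_per_block(self) -> int:
        return int(round(self.block_duration_s / self.tr_s))

    @property
    def fixation_volumes(self) -> int:
        return int(round(self.fixation_duration_s / self.tr_s))


# --------------------------------------------------------------------------
# Cortical sheet: ocular dominance and spatial-frequency preference maps
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Flattened cortical patch: physical extent and pixel size, in mm."""

    extent_mm: tuple[float, float] = (24.0, 24.0)
    mm_per_px: float = 0.15

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if min(self.extent_mm) <= 0:
            raise ValueError("extent must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.extent_mm[0] / self.mm_per_px)),
            int(round(self.extent_mm[1] / self.mm_per_px)),
        )


@dataclass
class CorticalSheet:
    """Ground-truth columnar maps on a mm-resolved grid.

    ``ocularity`` is in [-1, +1] (+1 fully left-eye, -1 fully right-eye);
    ``sf_pref`` is the preferred spatial frequency on a [0, 1] axis.
    """

    grid: GridSpec
    ocularity: np.ndarray
    sf_pref: np.ndarray
    od_period_mm: float
    coupling_rho: float
    seed: int


def _bandpass_noise(shape, mm_per_px, period_mm, rng, width_octaves=0.25):
    """White Gaussian noise band-passed around spatial frequency 1/period_mm.

    The filter is a log-Gaussian annulus in the 2D Fourier plane; the DC
    component is zeroed, so the output has exactly zero mean.
    """
    noise = rng.standard_normal(shape)
    fx = np.fft.fftfreq(shape[0], d=mm_per_px)
    fy = np.fft.fftfreq(shape[1], d=mm_per_px)
    f = np.hypot(fx[:, None], fy[None, :])
    f0 = 1.0 / period_mm
    with np.errstate(divide="ignore"):
        logratio = np.log2(np.where(f > 0, f / f0, np.inf))
    gain = np.exp(-(logratio**2) / (2.0 * width_octaves**2))
    gain[f == 0] = 0.0
    out = np.fft.ifft2(np.fft.fft2(noise) * gain).real
    sd = out.std()
    if sd == 0:
        raise ValueError("degenerate band-pass output (grid too small?)")
    return out / sd


def generate_od_map(
    grid: GridSpec,
    od_period_mm: float = 1.6,
    sharpness: float = 3.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate an ocular dominance map with a controlled columnar period.

    Band-pass-filtered Gaussian noise (annular filter centered on
    ``1/od_period_mm``) is passed through a tanh saturation of the given
    ``sharpness``; ``sharpness = 0`` returns the linear field rescaled to
    [-1, 1].  The radially averaged power spectrum of the result peaks at
    ``1/od_period_mm`` (within half an octave).

    Parameters
    ----------
    grid
        Sheet geometry; must span at least two columnar periods per axis.
    od_period_mm
        Full left+right period of the column pattern (~2 x 0.8 mm).
    sharpness
        >= 0; larger values push ocularity toward the +/-1 rails
        (more binary, stripe-like columns).
    """
    if sharpness < 0:
        raise ValueError("sharpness must be >= 0")
    if min(grid.extent_mm) < 2 * od_period_mm:
        raise ValueError(
            f"grid extent {grid.extent_mm} mm spans fewer than two OD periods "
            f"({od_period_mm} mm); the map would be a single column"
        )
    rng = np.random.default_rng(seed)
    base = _bandpass_noise(grid.shape, grid.mm_per_px, od_period_mm, rng)
    if sharpness == 0:
        return base / np.abs(base).max()
    return np.tanh(sharpness * base)


def generate_sf_map(
    ocularity: np.ndarray,
    coupling_rho: float,
    mm_per_px: float = 0.15,
    period_mm: float = 1.6,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate a spatial-frequency preference map in [0, 1].

    ``coupling_rho`` mixes a field derived from ``1 - |ocularity|`` (so that
    low-sf preference concentrates at column centers, where |ocularity| is
    high) with independent band-passed noise.  rho = 0 gives an independent
    map; rho = 1 makes sf preference a deterministic function of the OD map.
    """
    if not 0.0 <= coupling_rho <= 1.0:
        raise ValueError("coupling_rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    oc = np.asarray(ocularity, dtype=float)

    def _standardize(x):
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 0 else 1.0)

    target = _standardize(-np.abs(oc))  # high where |ocularity| is low
    indep = _bandpass_noise(oc.shape, mm_per_px, period_mm, rng)
    g = coupling_rho * target + (1.0 - coupling_rho) * indep
    lo, hi = g.min(), g.max()
    if hi == lo:
        return np.full_like(g, 0.5)
    return (g - lo) / (hi - lo)


def make_cortical_sheet(
    grid: GridSpec | None = None,
    od_period_mm: float = 1.6,
    coupling_rho: float = 0.9,
    sharpness: float = 3.0,
    seed: int = 0,
) -> CorticalSheet:
    """Convenience constructor: OD map plus coupled sf-preference map."""
    grid = grid or GridSpec()
    ss = np.random.SeedSequence(seed)
    s_od, s_sf = ss.spawn(2)
    oc = generate_od_map(grid, od_period_mm, sharpness, np.random.default_rng(s_od))
    sf = generate_sf_map(
        oc, coupling_rho, grid.mm_per_px, od_period_mm, np.random.default_rng(s_sf)
    )
    return CorticalSheet(grid, oc, sf, od_period_mm, coupling_rho, seed)


def radial_power_spectrum(field: np.ndarray, mm_per_px: float, n_bins: int = 40):
    """Radially averaged 2D power spectrum.

    Returns (bin center frequencies in cycles/mm, mean power per bin),
    excluding the DC bin.
    """
    power = np.abs(np.fft.fft2(field - field.mean())) ** 2
    fx = np.fft.fftfreq(field.shape[0], d=mm_per_px)
    fy = np.fft.fftfreq(field.shape[1], d=mm_per_px)
    f = np.hypot(fx[:, None], fy[None, :]).ravel()
    p = power.ravel()
    fmax = 0.5 / mm_per_px
    edges = np.linspace(0, fmax, n_bins + 1)
    idx = np.digitize(f, edges) - 1
    keep = (idx >= 0) & (idx < n_bins) & (f > 0)
    sums = np.bincount(idx[keep], weights=p[keep], minlength=n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_p = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, mean_p


# --------------------------------------------------------------------------
# Neural response model and voxel sampling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseModel:
    """Forward model from (stimulus, sheet) to a neural response field.

    response(eye, sf) = base_gain * tune(|sf - sf_pref|)
                        * (1 + eye_selectivity * sign(eye) * ocularity)
                        + left_eye_offset_delta * [eye == L]

    with sign(L) = +1, sign(R) = -1 and a Gaussian sf tuning curve of width
    ``sf_tuning_width`` on the [0, 1] preference axis.  The additive
    ``left_eye_offset_delta`` models a small global mean-signal advantage for
    left-eye stimulation, independent of the columnar pattern.

    Noise parameters apply at the volume level: per-voxel Gaussian noise of
    marginal SD ``noise_sd`` with AR(1) temporal autocorrelation ``ar1_phi``.
    """

    base_gain: float = 1.0
    eye_selectivity: float = 0.8
    sf_tuning_width: float = 0.3
    left_eye_offset_delta: float = 0.02
    noise_sd: float = 0.3
    ar1_phi: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.eye_selectivity <= 1.0:
            raise ValueError("eye_selectivity must lie in [0, 1] (keeps response >= 0)")
        if self.sf_tuning_width <= 0:
            raise ValueError("sf_tuning_width must be positive")
        if self.left_eye_offset_delta < 0:
            raise ValueError("left_eye_offset_delta must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in [0, 1)")


def neural_response(
    sheet: CorticalSheet, eye: str, sf, model: ResponseModel
) -> np.ndarray:
    """Noise-free neural response field for one stimulus.

    ``sf`` may be a condition token ("low"/"high") or a float on the [0, 1]
    preference axis.
    """
    if eye not in EYES:
        raise ValueError(f"unknown eye token {eye!r}")
    if isinstance(sf, str):
        if sf not in SF_AXIS:
            raise ValueError(f"unknown sf token {sf!r}")
        sf_stim = SF_AXIS[sf]
    else:
        sf_stim = float(sf)
        if not 0.0 <= sf_stim <= 1.0:
            raise ValueError("stimulus sf must lie on the [0, 1] preference axis")
    s = 1.0 if eye == "L" else -1.0
    tune = np.exp(
        -((sf_stim - sheet.sf_pref) ** 2) / (2.0 * model.sf_tuning_width**2)
    )
    resp = model.base_gain * tune * (1.0 + model.eye_selectivity * s * sheet.ocularity)
    if eye == "L":
        resp = resp + model.left_eye_offset_delta
    return resp


@dataclass(frozen=True)
class VoxelSamplingConfig:
    """How the voxel grid samples the cortical sheet.

    Each voxel averages the sheet pixels inside its square footprint
    (``voxel_mm`` on a side); the resulting voxel image is then smoothed
    with a Gaussian kernel of FWHM ``smoothing_fwhm_mm``, emulating the
    moderate spatial smoothing applied to the functional data.  Because the
    columnar period (~1.6 mm) is close to the voxel pitch (1.5 mm), the box
    average aliases the column pattern down to low spatial frequencies that
    survive the smoothing — the voxel eye biases the decoder relies on.
    """

    voxel_mm: float = 1.5
    smoothing_fwhm_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")


def sample_voxels(
    field: np.ndarray, config: VoxelSamplingConfig, mm_per_px: float
) -> np.ndarray:
    """Sample a sheet field into a 2D voxel image.

    Pixels are assigned to voxels by position; only complete voxel
    footprints are kept (trailing partial voxels are dropped).  A constant
    field yields constant voxels for any smoothing.
    """
    field = np.asarray(field, dtype=float)
    px_per_vox = config.voxel_mm / mm_per_px
    nvx = int(field.shape[0] * mm_per_px / config.voxel_mm)
    nvy = int(field.shape[1] * mm_per_px / config.voxel_mm)
    if nvx < 1 or nvy < 1:
        raise ValueError("voxel grid does not fit on the sheet")
    ix = np.floor(np.arange(field.shape[0]) / px_per_vox).astype(int)
    iy = np.floor(np.arange(field.shape[1]) / px_per_vox).astype(int)
    keep_x = ix < nvx
    keep_y = iy < nvy
    sub = field[np.ix_(keep_x, keep_y)]
    vx = ix[keep_x]
    vy = iy[keep_y]
    flat_idx = (vx[:, None] * nvy + vy[None, :]).ravel()
    counts = np.bincount(flat_idx, minlength=nvx * nvy)
    if np.any(counts == 0):
        raise ValueError("empty voxel footprint")
    sums = np.bincount(flat_idx, weights=sub.ravel(), minlength=nvx * nvy)
    vox = (sums / counts).reshape(nvx, nvy)
    if config.smoothing_fwhm_mm > 0:
        sigma_vox = config.smoothing_fwhm_mm / 2.3548200450309493 / config.voxel_mm
        vox = ndimage.gaussian_filter(vox, sigma_vox, mode="nearest")
    return vox


# --------------------------------------------------------------------------
# Hemodynamics and run simulation
# --------------------------------------------------------------------------


def double_gamma_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR (peak 6 s, undershoot 16 s)."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration_s, tr_s)
    peak = gamma_dist.pdf(t, a=6, scale=1.0)
    under = gamma_dist.pdf(t, a=16, scale=1.0)
    h = peak - under / 6.0
    return h / h.max()


def _block_regressor(onset_vol, n_vols, total_vols, hrf: str, tr_s: float):
    box = np.zeros(total_vols)
    box[onset_vol : onset_vol + n_vols] = 1.0
    if hrf == "boxcar":
        return box
    if hrf == "gamma":
        kernel = double_gamma_hrf(tr_s)
        reg = np.convolve(box, kernel)[:total_vols]
        # unit plateau so the block expectation matches the response vector
        return reg / max(reg.max(), 1e-12)
    raise ValueError(f"unknown hrf mode {hrf!r}")


def _ar1_noise(rng, n_voxels, n_volumes, sd, phi):
    if sd == 0:
        return np.zeros((n_voxels, n_volumes))
    e = rng.standard_normal((n_voxels, n_volumes))
    e *= sd * np.sqrt(1.0 - phi**2)
    e[:, 0] = e[:, 0] / np.sqrt(1.0 - phi**2)  # stationary start
    return signal.lfilter([1.0], [1.0, -phi], e, axis=1)


def simulate_run(
    design: ExperimentDesign,
    condition_responses: Mapping[str, np.ndarray],
    model: ResponseModel,
    run_index: int,
    order_seed: int | np.random.Generator = 0,
    noise_seed: int | np.random.Generator = 1,
    hrf: str = "gamma",
) -> RunData:
    """Simulate one block-design run.

    The run starts with a fixation block, then each condition appears once
    (pseudo-random order drawn from ``order_seed``) followed by fixation.
    Stimulation volumes have noise-free expectation equal to the condition's
    voxel response vector scaled by the HRF-shaped regressor; fixation
    volumes have expectation zero.  AR(1) Gaussian noise (from
    ``noise_seed``) is added throughout.  Volume labels follow the block
    timing, not the hemodynamic lag.
    """
    missing = [c for c in design.conditions if c not in condition_responses]
    if missing or len(condition_responses) != len(design.conditions):
        raise ValueError(
            f"condition responses {sorted(condition_responses)} do not match "
            f"design conditions {list(design.conditions)}"
        )
    shapes = {np.asarray(v).shape for v in condition_responses.values()}
    if len(shapes) != 1:
        raise ValueError("all condition response vectors must have the same length")

    order_rng = np.random.default_rng(order_seed)
    order = [design.conditions[i] for i in order_rng.permutation(len(design.conditions))]

    vpb = design.volumes_per_block
    vpf = design.fixation_volumes
    total = vpf + len(order) * (vpb + vpf)
    n_vox = len(next(iter(condition_responses.values())))

    data = np.zeros((n_vox, total))
    labels = [FIXATION] * total
    for i, cond in enumerate(order):
        onset = vpf + i * (vpb + vpf)
        reg = _block_regressor(onset, vpb, total, hrf, design.tr_s)
        data += np.outer(np.asarray(condition_responses[cond], dtype=float), reg)
        for t in range(onset, onset + vpb):
            labels[t] = cond

    noise_rng = np.random.default_rng(noise_seed)
    data += _ar1_noise(noise_rng, n_vox, total, model.noise_sd, model.ar1_phi)
    return RunData(data=data, volume_labels=labels, tr_s=design.tr_s, run_index=run_index)


@dataclass
class GroundTruth:
    """Everything needed to verify recovery from a simulated dataset."""

    sheet: CorticalSheet
    model: ResponseModel
    sampling: VoxelSamplingConfig
    design: ExperimentDesign
    condition_responses: dict[str, np.ndarray]
    voxel_shape: tuple[int, int]
    seed: int


def condition_voxel_responses(
    sheet: CorticalSheet, model: ResponseModel, sampling: VoxelSamplingConfig
) -> tuple[dict[str, np.ndarray], tuple[int, int]]:
    """Noise-free voxel response vector per condition (and the voxel grid shape)."""
    out = {}
    shape = None
    for cond in CONDITIONS:
        eye, sf = cond.split("_")
        fld = neural_response(sheet, eye, sf, model)
        vox = sample_voxels(fld, sampling, sheet.grid.mm_per_px)
        shape = vox.shape
        out[cond] = vox.ravel()
    return out, shape


def simulate_experiment(
    design: ExperimentDesign | None = None,
    sheet: CorticalSheet | None = None,
    model: ResponseModel | None = None,
    sampling: VoxelSamplingConfig | None = None,
    seed: int = 0,
    hrf: str = "gamma",
) -> tuple[list[RunData], GroundTruth]:
    """Simulate a full multi-run session plus its ground-truth record."""
    design = design or ExperimentDesign()
    model = model or ResponseModel()
    sampling = sampling or VoxelSamplingConfig()
    if sheet is None:
        sheet = make_cortical_sheet(seed=seed)
    responses, vox_shape = condition_voxel_responses(sheet, model, sampling)
    cond_resp = {c: responses[c] for c in design.conditions}

    ss = np.random.SeedSequence(seed)
    run_seeds = ss.spawn(design.n_runs)
    runs = []
    for r, rs in enumerate(run_seeds):
        s_order, s_noise = rs.spawn(2)
        runs.append(
            simulate_run(
                design,
                cond_resp,
                model,
                run_index=r,
                order_seed=np.random.default_rng(s_order),
                noise_seed=np.random.default_rng(s_noise),
                hrf=hrf,
            )
        )
    gt = GroundTruth(
        sheet=sheet,
        model=model,
        sampling=sampling,
        design=design,
        condition_responses=cond_resp,
        voxel_shape=vox_shape,
        seed=seed,
    )
    return runs, gt


# --------------------------------------------------------------------------
# Behavioral session simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BehavioralDesign:
    """Out-of-scanner utrocular discrimination session.

    624 brief (350 ms) monocular presentations; the same condition never
    appears twice in a row and the same spatial frequency never repeats on
    adjacent trials within any 8-trial window.  Responses come from an
    equal-variance Gaussian signal-detection observer whose sensitivity to
    "dominant eye stimulated" and response criterion are set per spatial
    frequency; defaults reproduce the group-average behavioral regime
    (essentially no sensitivity at the low spatial frequency, clear
    sensitivity at the high one, near-neutral criteria).
    """

    n_trials: int = 624
    stimulus_duration_ms: float = 350.0
    dprime_per_sf: Mapping[str, float] = field(
        default_factory=lambda: {"low": -0.13, "high": 0.96}
    )
    criterion_per_sf: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.07, "high": 0.16}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        for m in (self.dprime_per_sf, self.criterion_per_sf):
            if set(m) != set(SFS):
                raise ValueError(f"need one value per sf level {SFS}, got {sorted(m)}")


def check_sequence_constraints(conditions: Sequence[str]) -> bool:
    """Exhaustively verify both ordering rules on a condition sequence.

    Rule 1: no two adjacent trials share a condition.  Rule 2: within any 8
    consecutive trials the same spatial frequency never occurs twice in a
    row (equivalent to global alternation of sf, since every adjacent pair
    lies inside some 8-trial window).
    """
    sfs = [c.split("_")[1] for c in conditions]
    for i in range(len(conditions) - 1):
        if conditions[i] == conditions[i + 1]:
            return False
    for start in range(max(1, len(conditions) - 7)):
        window = sfs[start : start + 8]
        for j in range(len(window) - 1):
            if window[j] == window[j + 1]:
                return False
    return True


def _generate_trial_sequence(n_trials: int, rng, max_retries: int = 100_000):
    """Balanced condition sequence satisfying both ordering constraints.

    Spatial frequency strictly alternates (which enforces rule 2 and makes
    rule 1 automatic); eyes are assigned by shuffling a balanced multiset
    within each sf stream.  The result is validated exhaustively; failure to
    find a valid sequence inside the retry budget is an error.
    """
    for _ in range(max_retries):
        first_sf = SFS[rng.integers(2)]
        sf_seq = [first_sf if i % 2 == 0 else SFS[1 - SFS.index(first_sf)]
                  for i in range(n_trials)]
        conds = [None] * n_trials
        for sf_level in SFS:
            slots = [i for i, s in enumerate(sf_seq) if s == sf_level]
            n_left = len(slots) // 2
            eyes = np.array(["L"] * n_left + ["R"] * (len(slots) - n_left), dtype=object)
            rng.shuffle(eyes)
            for i, e in zip(slots, eyes):
                conds[i] = condition_label(e, sf_level)
        if check_sequence_constraints(conds):
            return conds
    raise RuntimeError(
        f"no constraint-satisfying sequence found within {max_retries} retries"
    )


def simulate_behavior(
    design: BehavioralDesign | None = None,
    dominant_eye: str = "L",
    subject_id: str = "sim",
    seed: int | None = None,
) -> BehavioralSession:
    """Simulate one utrocular-discrimination session.

    On each trial the observer receives internal evidence
    ``x ~ N(d'_sf, 1)`` when the dominant eye is stimulated and
    ``x ~ N(0, 1)`` otherwise, and responds "dominant eye" when ``x``
    exceeds ``criterion_sf + d'_sf / 2`` (the equal-variance likelihood
    threshold shifted by the response bias c).
    """
    design = design or BehavioralDesign()
    if dominant_eye not in EYES:
        raise ValueError(f"unknown eye token {dominant_eye!r}")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    conds = _generate_trial_sequence(design.n_trials, rng)
    stim_eye = np.array([c.split("_")[0] for c in conds], dtype=object)
    sf = np.array([c.split("_")[1] for c in conds], dtype=object)

    d = np.array([design.dprime_per_sf[s] for s in sf])
    c = np.array([design.criterion_per_sf[s] for s in sf])
    is_signal = stim_eye == dominant_eye
    x = np.where(is_signal, d, 0.0) + rng.standard_normal(design.n_trials)
    say_dominant = x > (c + d / 2.0)
    other = "R" if dominant_eye == "L" else "L"
    resp_eye = np.where(say_dominant, dominant_eye, other).astype(object)

    return BehavioralSession(
        stimulus_eye=stim_eye,
        sf=sf,
        response_eye=resp_eye,
        dominant_eye=dominant_eye,
        subject_id=subject_id,
    )
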