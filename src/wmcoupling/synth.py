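"""Synthetic multimodal participants with known ground-truth coupling.

A synthetic participant consists of:

* white-matter contacts scattered in a box with a minimum separation
  that guarantees disjoint voxel-sphere ROIs;
* a sparse, distance-dependent structural network whose integer edge
  weights are realized as explicit streamline polylines (so streamline
  counting recovers the weights exactly);
* LFP-like neural dynamics from a stable linear stochastic network
  model driven by 1/f-shaped innovations, in which pairwise
  synchronization increases with structural edge weight;
* BOLD-like signals obtained by convolving a slow activity envelope of
  the neural process with a canonical double-gamma hemodynamic
  response, sampled at the TR, plus white measurement noise;
* optionally, a 4D voxel volume with each contact's BOLD signal painted
  into its 19-voxel sphere.

Everything is a pure function of (config, seed): the study-level seed
deterministically spawns independent per-stage substreams, so each
stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .datatypes import (
    BoldVolume,
    ContactSet,
    StreamlineSet,
    TimeSeriesPanel,
    ValidationError,
    WmCouplingError,
)
from .geometry import densify_polyline, mm_to_voxel, sphere_offsets

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SynthError",
    "UnstableCouplingError",
    "generate_contacts",
    "generate_structural_network",
    "simulate_neural_dynamics",
    "simulate_bold",
    "render_bold_volume",
    "generate_participant",
    "SyntheticParticipant",
    "canonical_hrf",
    "hemodynamic_convolve",
]


class SynthError(WmCouplingError):
    """Synthetic-study generation failure (packing, degenerate network...)."""


class UnstableCouplingError(SynthError):
    """The coupled transition matrix has spectral radius >= 1."""


# Named RNG substreams spawned from the study seed.
_STAGES = {"contacts": 0, "structure": 1, "lfp": 2, "bold": 3, "render": 4}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES[stage],))
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic participant.

    Acquisition defaults mirror the clinical recordings the generator
    stands in for: 2000 Hz LFP for 60 s, TR 2 s with 240 volumes on a
    2 mm isotropic grid, and 47 white-matter contacts (hence
    47*46/2 = 1081 regional pairs).

    ``coupling_strength`` is the unitless gain mapping normalized
    structural weight to dynamic coupling.  With the default dynamics
    constants (``ar_retention`` = 0.5, ``coupling_gain`` = 0.9) the
    model is stable for coupling_strength < (1 - 0.5)/0.9 ~ 0.556 and
    sits near criticality at 0.5, where the strongest edges reach
    pairwise correlations around 0.4-0.6.
    """

    n_contacts: int = 47
    box_extent: float = 120.0  # mm per axis
    sc_density: float = 0.6  # edge-probability scale in (0, 1]
    distance_decay: float = 0.03  # 1/mm decline of edge probability
    coupling_strength: float = 0.5
    lfp_fs: float = 2000.0  # Hz
    lfp_duration: float = 60.0  # s
    bold_tr: float = 2.0  # s
    bold_n_volumes: int = 240
    bold_voxel_mm: float = 2.0
    noise_sd_lfp: float = 0.1  # measurement noise, units of signal SD
    noise_sd_bold: float = 0.3  # scanner noise, units of signal SD
    seed: int = 0
    # dynamics and hemodynamics knobs
    ar_retention: float = 0.5  # per-sample self-memory of each node
    coupling_gain: float = 0.9  # scales dynamic_coupling inside the transition
    burn_in_s: float = 10.0  # discarded transient
    envelope_window_s: float = 1.0  # moving-RMS window for the BOLD envelope
    envelope_fs: float = 10.0  # Hz at which the envelope is carried
    hrf_peak_s: float = 5.0
    hrf_undershoot_s: float = 15.0
    mean_streamlines: float = 3.0  # mean streamline count of present edges

    def __post_init__(self) -> None:
        if self.n_contacts < 2:
            raise ValidationError("need at least 2 contacts")
        if self.bold_n_volumes < 2:
            raise ValidationError("need at least 2 BOLD volumes")
        if not 0 < self.sc_density <= 1:
            raise ValidationError("sc_density must lie in (0, 1]")
        for name in (
            "distance_decay", "noise_sd_lfp", "noise_sd_bold", "burn_in_s",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "box_extent", "lfp_fs", "lfp_duration", "bold_tr", "bold_voxel_mm",
            "envelope_window_s", "envelope_fs", "mean_streamlines",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        n_samples = self.lfp_duration * self.lfp_fs
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValidationError(
                "lfp_duration x lfp_fs must be an integer number of samples"
            )

    @property
    def lfp_n_samples(self) -> int:
        return int(round(self.lfp_duration * self.lfp_fs))


@dataclass(frozen=True)
class GroundTruth:
    """The structural weights and the coupling actually simulated.

    ``dynamic_coupling`` = coupling_strength x sc_weights normalized to
    unit spectral radius — a monotone function of the structural weights
    whenever coupling_strength > 0, encoding the hypothesis that
    anatomical connectivity constrains functional dynamics.
    """

    sc_weights: np.ndarray
    dynamic_coupling: np.ndarray
    coupling_strength: float
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        sc = np.asarray(self.sc_weights, dtype=float)
        dc = np.asarray(self.dynamic_coupling, dtype=float)
        object.__setattr__(self, "sc_weights", sc)
        object.__setattr__(self, "dynamic_coupling", dc)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        n = len(self.node_ids)
        for name, m in (("sc_weights", sc), ("dynamic_coupling", dc)):
            if m.shape != (n, n):
                raise ValidationError(f"{name} shape {m.shape} != ({n}, {n})")
            if np.abs(m - m.T).max(initial=0.0) > 1e-12:
                raise ValidationError(f"{name} must be symmetric")
            if np.abs(np.diag(m)).max(initial=0.0) > 0:
                raise ValidationError(f"{name} must have zero diagonal")
        if (sc < 0).any():
            raise ValidationError("sc_weights must be nonnegative")


def generate_contacts(cfg: SynthConfig) -> ContactSet:
    """Scatter white-matter contacts uniformly with guaranteed separation.

    Rejection sampling enforces (a) Euclidean separation >= 2 x voxel
    size and (b) centre-voxel Chebyshev distance >= 3 voxels, so the
    27-voxel sphere ROIs of any two contacts are disjoint.  Contacts
    stay one ROI-width clear of the box faces so their spheres are fully
    in-grid.  Fails if the box cannot accommodate the contacts within a
    bounded number of attempts.
    """
    rng = _stage_rng(cfg.seed, "contacts")
    vox = cfg.bold_voxel_mm
    margin = 2.0 * vox
    if cfg.box_extent <= 2 * margin:
        raise SynthError("box_extent too small for the ROI margin")
    min_sep = 2.0 * vox
    coords = np.empty((cfg.n_contacts, 3))
    voxels = np.empty((cfg.n_contacts, 3), dtype=int)
    n_placed = 0
    max_attempts = 500 * cfg.n_contacts
    attempts = 0
    while n_placed < cfg.n_contacts:
        if attempts >= max_attempts:
            raise SynthError(
                f"could not place {cfg.n_contacts} contacts with >= {min_sep} mm "
                f"separation in a {cfg.box_extent} mm box after {attempts} attempts"
            )
        attempts += 1
        cand = rng.uniform(margin, cfg.box_extent - margin, size=3)
        cand_vox = mm_to_voxel(cand, vox, np.zeros(3))[0]
        if n_placed:
            dist_ok = (
                np.linalg.norm(coords[:n_placed] - cand, axis=1) >= min_sep
            ).all()
            vox_ok = (
                np.abs(voxels[:n_placed] - cand_vox).max(axis=1) >= 3
            ).all()
            if not (dist_ok and vox_ok):
                continue
        coords[n_placed] = cand
        voxels[n_placed] = cand_vox
        n_placed += 1
    ids = tuple(f"c{k:03d}" for k in range(cfg.n_contacts))
    return ContactSet(ids=ids, coords=coords, tissue=("white",) * cfg.n_contacts)


def _emit_streamline(
    rng: np.random.Generator,
    a: np.ndarray,
    b: np.ndarray,
    other_contacts: np.ndarray,
    clearance_mm: float,
    endpoint_jitter_mm: float = 1.0,
    n_vertices: int = 12,
    max_tries: int = 200,
) -> np.ndarray:
    """One polyline from near ``a`` to near ``b`` avoiding other contacts.

    Quadratic Bezier arc with a random perpendicular bow; candidates
    whose densified path comes within ``clearance_mm`` of any third
    contact are rejected and re-drawn with a fresh bow.
    """
    for attempt in range(max_tries):
        p0 = a + rng.normal(scale=endpoint_jitter_mm / 3.0, size=3)
        p2 = b + rng.normal(scale=endpoint_jitter_mm / 3.0, size=3)
        bow = rng.normal(scale=3.0 + attempt * 0.2, size=3)
        p1 = 0.5 * (p0 + p2) + bow
        t = np.linspace(0.0, 1.0, n_vertices)[:, None]
        line = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        if other_contacts.size == 0:
            return line
        dense = densify_polyline(line, 0.5)
        d = np.linalg.norm(
            dense[:, None, :] - other_contacts[None, :, :], axis=2
        ).min()
        if d > clearance_mm:
            return line
    raise SynthError(
        "could not route a streamline clear of other contacts; geometry too dense"
    )


def generate_structural_network(
    contacts: ContactSet, cfg: SynthConfig
) -> tuple[GroundTruth, StreamlineSet]:
    """Sparse distance-dependent structural network with explicit streamlines.

    Edge (i, j) is present with probability
    ``sc_density * exp(-distance_decay * d_ij)`` and carries an integer
    streamline count >= 1 (1 + Poisson).  Each counted streamline is
    emitted as a polyline whose endpoints lie within 2 mm of the two
    contacts and whose path stays clear of every other contact's
    counting sphere, so :func:`~wmcoupling.geometry.count_streamline_connections`
    recovers ``sc_weights`` exactly.
    """
    if len(contacts) < 2:
        raise SynthError("need at least 2 contacts")
    rng = _stage_rng(cfg.seed, "structure")
    coords = contacts.coords
    n = len(contacts)
    sc = np.zeros((n, n))
    lines: list[np.ndarray] = []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            p = min(1.0, cfg.sc_density * np.exp(-cfg.distance_decay * d))
            if rng.uniform() >= p:
                continue
            weight = 1 + rng.poisson(max(cfg.mean_streamlines - 1.0, 0.0))
            sc[i, j] = sc[j, i] = weight
            others = np.delete(coords, [i, j], axis=0)
            for _ in range(int(weight)):
                lines.append(
                    _emit_streamline(rng, coords[i], coords[j], others, clearance_mm=2.5)
                )
    if sc.sum() == 0:
        raise SynthError(
            "structural network is empty: sc_density/distance_decay leave no "
            "edge probability mass at this geometry"
        )
    radius = np.max(np.abs(np.linalg.eigvalsh(sc)))
    dynamic = cfg.coupling_strength * sc / radius
    truth = GroundTruth(
        sc_weights=sc,
        dynamic_coupling=dynamic,
        coupling_strength=cfg.coupling_strength,
        node_ids=contacts.ids,
    )
    return truth, StreamlineSet(streamlines=tuple(lines))


def _pink_noise(
    rng: np.random.Generator, n_nodes: int, n_samples: int, fs: float
) -> np.ndarray:
    """Broadband innovations with an approximately 1/f-shaped spectrum.

    A single white stream shaped by a white floor plus three
    first-order (leaky-integrator) filters with cutoffs at 0.3, 3 and
    30 Hz, each normalized to unit stationary variance — a cascade
    approximation whose slope is set by the component weights.  The
    slowest component gives the activity envelope genuine infra-slow
    fluctuations, which is what the hemodynamic model samples.
    """
    w = rng.standard_normal((n_nodes, n_samples))
    out = 0.5 * w
    for cutoff_hz in (0.3, 3.0, 30.0):
        pole = float(np.exp(-2.0 * np.pi * cutoff_hz / fs))
        comp = signal.lfilter([1.0], [1.0, -pole], w, axis=1)
        out += np.sqrt(1.0 - pole**2) * comp  # unit stationary variance
    return out


def _transition_matrix(truth: GroundTruth, cfg: SynthConfig) -> np.ndarray:
    """Node transition A = ar_retention * I + coupling_gain * dynamic_coupling."""
    n = len(truth.node_ids)
    a = cfg.ar_retention * np.eye(n) + cfg.coupling_gain * truth.dynamic_coupling
    radius = float(np.max(np.abs(np.linalg.eigvalsh(a))))
    if radius >= 1.0:
        raise UnstableCouplingError(
            f"transition matrix spectral radius {radius:.3f} >= 1; reduce "
            f"coupling_strength below "
            f"{(1.0 - cfg.ar_retention) / cfg.coupling_gain:.3f}"
        )
    return a

def _simulate_var(
    a: np.ndarray, innovations: np.ndarray
) -> np.ndarray:
    """Exact simulation of x[t] = A x[t-1] + e[t] from zero initial state.

    A is symmetric, so the system diagonalizes into independent scalar
    AR(1) modes, each integrated with a vectorized linear filter.
    """
    lam, v = np.linalg.eigh(a)
    e_rot = v.T @ innovations
    x_rot = np.empty_like(e_rot)
    for k, pole in enumerate(lam):
        x_rot[k] = signal.lfilter([1.0], [1.0, -float(pole)], e_rot[k])
    return v @ x_rot


def simulate_neural_dynamics(truth: GroundTruth, cfg: SynthConfig) -> TimeSeriesPanel:
    """LFP-like signals from a stable linear stochastic network model.

    Discrete-time dynamics x[t] = A x[t-1] + e[t] with symmetric
    transition A (see :func:`SynthConfig`) and 1/f-shaped broadband
    innovations.  A ``burn_in_s`` transient is discarded, each channel
    is standardized to unit variance, and white measurement noise of SD
    ``noise_sd_lfp`` is added.  Pairwise correlation increases with
    dynamic coupling; with coupling_strength = 0 channels are
    independent.
    """
    a = _transition_matrix(truth, cfg)
    rng = _stage_rng(cfg.seed, "lfp")
    n = len(truth.node_ids)
    burn = int(round(cfg.burn_in_s * cfg.lfp_fs))
    total = burn + cfg.lfp_n_samples
    e = _pink_noise(rng, n, total, cfg.lfp_fs)
    x = _simulate_var(a, e)[:, burn:]
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    x = x / np.where(sd > 0, sd, 1.0)
    if cfg.noise_sd_lfp > 0:
        x = x + cfg.noise_sd_lfp * rng.standard_normal(x.shape)
    return TimeSeriesPanel(
        values=x, fs=cfg.lfp_fs, channel_ids=truth.node_ids, modality="seeg"
    )


def canonical_hrf(
    dt: float, peak_s: float = 5.0, undershoot_s: float = 15.0,
    undershoot_ratio: float = 1.0 / 6.0, length_s: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled every ``dt`` s.

    Gamma densities with unit scale peaking at ``peak_s`` and
    ``undershoot_s`` (shape = peak + 1), the undershoot weighted by
    ``undershoot_ratio``; normalized to unit peak.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0.0, length_s, dt)
    peak = gamma_dist.pdf(t, a=peak_s + 1.0, scale=1.0)
    under = gamma_dist.pdf(t, a=undershoot_s + 1.0, scale=1.0)
    hrf = peak - undershoot_ratio * under
    return hrf / np.abs(hrf).max()


def hemodynamic_convolve(
    envelope: np.ndarray, env_fs: float, tr: float, n_volumes: int,
    peak_s: float = 5.0, undershoot_s: float = 15.0,
) -> np.ndarray:
    """Convolve activity envelopes with the canonical HRF and sample at TR.

    ``envelope`` is (nodes, samples) at ``env_fs``; the causal
    convolution is sampled every ``tr`` seconds from t = 0.  Raises if
    the envelope is too short to cover ``n_volumes`` scans.
    """
    env = np.atleast_2d(np.asarray(envelope, dtype=float))
    hrf = canonical_hrf(1.0 / env_fs, peak_s=peak_s, undershoot_s=undershoot_s)
    step = tr * env_fs
    idx = np.round(np.arange(n_volumes) * step).astype(int)
    if idx[-1] >= env.shape[1]:
        raise SynthError(
            f"envelope covers {env.shape[1] / env_fs:.1f} s but "
            f"{n_volumes} volumes at TR {tr} s need {idx[-1] / env_fs:.1f} s"
        )
    conv = signal.fftconvolve(env, hrf[None, :], mode="full", axes=1)[:, : env.shape[1]]
    return conv[:, idx]


def _activity_envelope(values: np.ndarray, fs: float, cfg: SynthConfig) -> np.ndarray:
    """Moving-RMS activity envelope downsampled to the envelope rate."""
    from scipy.ndimage import uniform_filter1d

    win = max(1, int(round(cfg.envelope_window_s * fs)))
    power = uniform_filter1d(values**2, size=win, axis=1, mode="nearest")
    rms = np.sqrt(np.maximum(power, 0.0))
    stride = max(1, int(round(fs / cfg.envelope_fs)))
    return rms[:, ::stride]


def simulate_bold(
    neural: TimeSeriesPanel, truth: GroundTruth, cfg: SynthConfig
) -> TimeSeriesPanel:
    """BOLD-like panel from slow activity envelopes of the neural process.

    Each node's moving-RMS envelope is convolved with the canonical
    double-gamma HRF and sampled at the TR.  If the recorded neural
    panel is shorter than the scan, the envelope is extended by
    continuing the same generative model with a dedicated substream —
    the modalities are acquired in separate sessions, so the extension
    shares the coupling structure but not the noise realization.
    Signals are standardized per node before white noise of SD
    ``noise_sd_bold`` is added.
    """
    rng = _stage_rng(cfg.seed, "bold")
    env = _activity_envelope(neural.values, neural.fs, cfg)
    need_s = cfg.bold_tr * cfg.bold_n_volumes + 1.0  # margin past the last scan
    have_s = env.shape[1] / cfg.envelope_fs
    if have_s < need_s:
        extra_s = need_s - have_s
        a = _transition_matrix(truth, cfg)
        burn = int(round(cfg.burn_in_s * cfg.lfp_fs))
        n_extra = burn + int(np.ceil(extra_s * cfg.lfp_fs))
        e = _pink_noise(rng, neural.n_channels, n_extra, cfg.lfp_fs)
        x = _simulate_var(a, e)[:, burn:]
        x = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        x = x / np.where(sd > 0, sd, 1.0)
        env = np.concatenate([env, _activity_envelope(x, cfg.lfp_fs, cfg)], axis=1)
    env = env - env.mean(axis=1, keepdims=True)
    bold = hemodynamic_convolve(
        env, cfg.envelope_fs, cfg.bold_tr, cfg.bold_n_volumes,
        peak_s=cfg.hrf_peak_s, undershoot_s=cfg.hrf_undershoot_s,
    )
    bold = bold - bold.mean(axis=1, keepdims=True)
    sd = bold.std(axis=1, keepdims=True)
    bold = bold / np.where(sd > 0, sd, 1.0)
    if cfg.noise_sd_bold > 0:
        bold = bold + cfg.noise_sd_bold * rng.standard_normal(bold.shape)
    return TimeSeriesPanel(
        values=bold, fs=1.0 / cfg.bold_tr, channel_ids=neural.channel_ids,
        modality="bold",
    )


def render_bold_volume(
    contacts: ContactSet, bold: TimeSeriesPanel, cfg: SynthConfig
) -> BoldVolume:
    """Paint each contact's BOLD signal into its 19-voxel sphere.

    The grid spans the contact box at ``bold_voxel_mm`` spacing with the
    origin at 0 mm.  Background voxels carry independent white noise of
    SD ``noise_sd_bold``; overlapping contact neighborhoods (prevented
    by the contact-separation constraint) or out-of-grid contacts raise.
    """
    if bold.channel_ids != contacts.ids:
        raise SynthError("BOLD panel channels do not match contacts")
    vox = cfg.bold_voxel_mm
    shape = (int(np.floor(cfg.box_extent / vox)) + 1,) * 3
    rng = _stage_rng(cfg.seed, "render")
    nt = bold.n_samples
    if cfg.noise_sd_bold > 0:
        data = cfg.noise_sd_bold * rng.standard_normal(shape + (nt,))
    else:
        data = np.zeros(shape + (nt,))
    offsets = sphere_offsets(19)
    painted: set[tuple[int, int, int]] = set()
    for k, center in enumerate(contacts.coords):
        cvox = mm_to_voxel(center, vox, np.zeros(3))[0]
        if np.any(cvox < 0) or np.any(cvox >= shape):
            raise SynthError(f"contact {contacts.ids[k]!r} outside the volume grid")
        voxels = cvox[None, :] + offsets
        if np.any(voxels < 0) or np.any(voxels >= shape):
            raise SynthError(
                f"sphere of contact {contacts.ids[k]!r} extends outside the grid"
            )
        for vx in map(tuple, voxels):
            if vx in painted:
                raise SynthError(
                    f"overlapping 19-voxel neighborhoods at contact {contacts.ids[k]!r}"
                )
            painted.add(vx)
            data[vx[0], vx[1], vx[2], :] = bold.values[k]
    return BoldVolume(data=data, voxel_mm=vox, origin_mm=np.zeros(3), tr=cfg.bold_tr)


@dataclass(frozen=True)
class SyntheticParticipant:
    """Everything generated for one synthetic participant."""

    config: SynthConfig
    contacts: ContactSet
    truth: GroundTruth
    streamlines: StreamlineSet
    seeg: TimeSeriesPanel
    bold: TimeSeriesPanel
    volume: BoldVolume | None = None


def generate_participant(cfg: SynthConfig, render_volume: bool = False) -> SyntheticParticipant:
    """Generate a complete synthetic participant from one config."""
    contacts = generate_contacts(cfg)
    truth, streamlines = generate_structural_network(contacts, cfg)
    seeg = simulate_neural_dynamics(truth, cfg)
    bold = simulate_bold(seeg, truth, cfg)
    volume = render_bold_volume(contacts, bold, cfg) if render_volume else None
    return SyntheticParticipant(
        config=cfg, contacts=contacts, truth=truth, streamlines=streamlines,
        seeg=seeg, bold=bold, volume=volume,
    )
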