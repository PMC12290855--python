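"""Synthetic cerebro-spinal resting-state phantom.

Generates paired brain/cord 4D datasets with a planted somatotopic
coupling structure: seven cervical cord segments, each sharing a latent
spontaneous-event signal with one patch of a 1-D cortical sensorimotor
strip, plus cardiac/respiratory sinusoids, CSF compartments, slow drift
and motion traces.  Every downstream stage is testable against the
returned ground truth by parameter recovery.

Geometry (defaults):

* cord grid 6 x 6 x 42, 1 x 1 x 3 mm voxels: the central 4 x 4 in-plane
  core is gray matter, the surrounding ring is CSF; segments C1..C7 are
  equal-thickness slabs stacked along the third axis.
* cortex grid 42 x 14 x 3, 2 mm voxels: the sensorimotor strip occupies
  rows 2..11 of the second axis (the rest is CSF); seven patches tile the
  strip along the first axis, patch p preferentially coupled to segment p
  with geometrically decaying coupling to neighbours.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigurationError, ContractError, FormatError
from .types import BoldImage, LabelMap, MotionParams, PhysioTrace

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "hrf_kernel",
    "generate_phantom",
    "generate_cohort",
    "write_dataset",
    "read_dataset",
]

#: physiological trace sampling rate (Hz); traces are generated at high
#: rate and subsampled at volume times, so phase estimation sees
#: realistic inputs while the images see the aliased version.
PHYSIO_RATE_HZ = 100.0


@dataclass
class PhantomConfig:
    """All knobs of the synthetic phantom.

    ``coupling_snr`` is the ratio of the shared (neural) signal standard
    deviation to the idiosyncratic voxel noise standard deviation;
    ``coupling_falloff`` is the geometric decay of cortical coupling with
    segment distance.  Amplitudes are in the same arbitrary units as the
    neural signal (unit variance after HRF convolution).
    """

    n_subjects: int = 8
    tr_seconds: float = 1.55
    n_volumes: int = 230
    n_segments: int = 7
    cord_grid: tuple[int, int, int] = (6, 6, 42)
    cortex_grid: tuple[int, int, int] = (42, 14, 3)
    coupling_snr: float = 0.8
    coupling_falloff: float = 0.3
    event_rate: float = 0.05
    cardiac_hz: float = 1.0
    resp_hz: float = 0.3
    physio_amplitude_tissue: float = 0.25
    physio_amplitude_csf: float = 1.0
    drift_amplitude: float = 0.5
    motion_step_mm: float = 0.02
    motion_artifact_amplitude: float = 0.1
    baseline: float = 100.0
    hrf_peak_delay: float = 6.0
    hrf_undershoot_delay: float = 16.0
    hrf_undershoot_ratio: float = 6.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_volumes < 2:
            raise ConfigurationError("n_volumes must be >= 2")
        if self.n_segments < 2:
            raise ConfigurationError("n_segments must be >= 2")
        for name in ("cord_grid", "cortex_grid"):
            grid = getattr(self, name)
            if len(grid) != 3 or any(e < 1 for e in grid):
                raise ConfigurationError(f"{name} extents must all be >= 1")
        if self.cord_grid[2] % self.n_segments != 0:
            raise ConfigurationError(
                f"cord 3rd-axis extent {self.cord_grid[2]} not divisible by "
                f"n_segments {self.n_segments}"
            )
        if not self.tr_seconds > 0:
            raise ConfigurationError("tr_seconds must be positive")
        if not (0 <= self.event_rate <= 1):
            raise ConfigurationError("event_rate must lie in [0, 1]")
        if not self.coupling_snr > 0:
            raise ConfigurationError("coupling_snr must be positive (inf allowed)")


@dataclass
class GroundTruth:
    """Planted structure of one synthetic subject."""

    cord_labels: LabelMap
    cortex_labels: LabelMap
    event_trains: np.ndarray  # (S, T) nonnegative amplitudes
    coupling: np.ndarray  # (S, S), diagonal-dominant per row
    csf_masks: dict[str, np.ndarray]  # organ -> boolean mask
    motion: dict[str, MotionParams]  # organ -> params
    physio: tuple[PhysioTrace, PhysioTrace]  # (cardiac, respiratory)
    neural_signals: np.ndarray = field(default=None, repr=False)  # (S, T) HRF-convolved

    def __post_init__(self) -> None:
        S = self.event_trains.shape[0]
        if self.coupling.shape != (S, S):
            raise ContractError("coupling must be S x S")
        offdiag = self.coupling - np.diag(np.diag(self.coupling))
        if not np.all(np.diag(self.coupling) > offdiag.max(axis=1)):
            raise ContractError("coupling diagonal must dominate its row")

    @property
    def n_segments(self) -> int:
        return self.event_trains.shape[0]


def hrf_kernel(
    tr_seconds: float,
    duration_seconds: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at the TR.

    ``h(t) = g(t; peak_delay, 1) - g(t; undershoot_delay, 1) / ratio``
    with gamma densities of unit scale, so the positive lobe peaks at
    ``peak_delay - 1`` seconds (5 s for the default).  The kernel has
    ``ceil(duration / tr)`` samples and is normalized to max 1.
    """
    if not (tr_seconds > 0 and duration_seconds > 0):
        raise ContractError("tr and duration must be positive")
    n = math.ceil(duration_seconds / tr_seconds)
    t = np.arange(n) * tr_seconds

    def gpdf(t, shape):
        with np.errstate(divide="ignore"):
            logp = (shape - 1) * np.log(t) - t - gammaln(shape)
        out = np.where(t > 0, np.exp(logp), 0.0)
        return out

    h = gpdf(t, peak_delay) - gpdf(t, undershoot_delay) / undershoot_ratio
    return h / h.max()


def _segment_coupling(n_segments: int, falloff: float) -> np.ndarray:
    idx = np.arange(n_segments)
    return falloff ** np.abs(idx[:, None] - idx[None, :])


def _cord_geometry(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (segment label volume, csf mask) for the cord grid."""
    nx, ny, nz = config.cord_grid
    labels = np.zeros(config.cord_grid, dtype=np.int32)
    # gray-matter core: trim one voxel (or what the grid allows) per edge
    bx = 1 if nx > 2 else 0
    by = 1 if ny > 2 else 0
    core = np.zeros(config.cord_grid, dtype=bool)
    core[bx : nx - bx or None, by : ny - by or None, :] = True
    thickness = nz // config.n_segments
    z = np.arange(nz)
    seg_of_z = z // thickness + 1
    labels[core] = np.broadcast_to(seg_of_z, config.cord_grid)[core]
    csf = ~core
    return labels, csf


def _cortex_geometry(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (patch label volume, csf mask) for the cortex grid."""
    nx, ny, nz = config.cortex_grid
    by = max(1, ny // 7) if ny > 2 else 0
    strip = np.zeros(config.cortex_grid, dtype=bool)
    strip[:, by : ny - by or None, :] = True
    # patches tile the first axis as evenly as possible
    edges = np.linspace(0, nx, config.n_segments + 1)
    patch_of_x = np.minimum(np.searchsorted(edges, np.arange(nx), side="right"),
                            config.n_segments)
    labels = np.zeros(config.cortex_grid, dtype=np.int32)
    labels[strip] = np.broadcast_to(patch_of_x[:, None, None], config.cortex_grid)[strip]
    csf = ~strip
    return labels, csf


def _bounded_walk(rng: np.random.Generator, n: int, step: float, bound: float) -> np.ndarray:
    walk = np.cumsum(rng.normal(0.0, step, size=n))
    # reflect into [-bound, bound]
    walk = np.abs((walk + bound) % (4 * bound) - 2 * bound) - bound
    return walk


def _physio_traces(config: PhantomConfig, rng: np.random.Generator):
    duration = config.n_volumes * config.tr_seconds
    n = int(round(duration * PHYSIO_RATE_HZ)) + 1
    t = np.arange(n) / PHYSIO_RATE_HZ
    phase_c = rng.uniform(0, 2 * np.pi)
    phase_r = rng.uniform(0, 2 * np.pi)
    cardiac = np.cos(2 * np.pi * config.cardiac_hz * t + phase_c)
    resp = np.cos(2 * np.pi * config.resp_hz * t + phase_r)
    # cardiac peaks occur where the cosine phase crosses multiples of 2*pi
    k0 = math.ceil(phase_c / (2 * np.pi))
    k1 = math.floor((2 * np.pi * config.cardiac_hz * t[-1] + phase_c) / (2 * np.pi))
    peaks = (2 * np.pi * np.arange(k0, k1 + 1) - phase_c) / (2 * np.pi * config.cardiac_hz)
    peaks = peaks[(peaks >= 0) & (peaks <= t[-1])]
    card = PhysioTrace(cardiac, PHYSIO_RATE_HZ, "cardiac", peaks)
    belt = PhysioTrace(resp, PHYSIO_RATE_HZ, "respiratory")
    return card, belt


def _sample_at_volumes(trace: PhysioTrace, volume_times: np.ndarray) -> np.ndarray:
    return np.interp(volume_times, trace.times, trace.samples)


def _fd_power(motion: np.ndarray, organ: str, radius: float = 50.0) -> np.ndarray:
    d = np.abs(np.diff(motion, axis=0))
    if organ == "brain":
        fd = d[:, :3].sum(axis=1) + radius * d[:, 3:].sum(axis=1)
    else:
        fd = d.mean(axis=1)
    return np.concatenate([[0.0], fd])


def generate_phantom(config: PhantomConfig) -> tuple[BoldImage, BoldImage, GroundTruth]:
    """Generate one synthetic subject: (brain, cord, ground truth).

    Each cord gray-matter voxel carries the HRF-convolved event train of
    its segment plus white noise scaled by ``coupling_snr``; each
    cortical strip voxel carries a graded mixture of segment signals
    (geometric falloff around its preferred segment).  CSF voxels carry
    only physiological sinusoids, drift and noise.  Identical configs
    (including ``rng_seed``) reproduce bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    S, T = config.n_segments, config.n_volumes
    tr = config.tr_seconds
    volume_times = np.arange(T) * tr

    events = (rng.random((S, T)) < config.event_rate).astype(float)
    hrf = hrf_kernel(tr, peak_delay=config.hrf_peak_delay,
                     undershoot_delay=config.hrf_undershoot_delay,
                     undershoot_ratio=config.hrf_undershoot_ratio)
    neural = np.stack([np.convolve(ev, hrf)[:T] for ev in events])
    coupling = _segment_coupling(S, config.coupling_falloff)

    cord_labels_arr, cord_csf = _cord_geometry(config)
    cortex_labels_arr, cortex_csf = _cortex_geometry(config)

    card, belt = _physio_traces(config, rng)
    card_v = _sample_at_volumes(card, volume_times)
    belt_v = _sample_at_volumes(belt, volume_times)

    drift_phase = rng.uniform(0, 2 * np.pi, size=2)
    total = T * tr
    drifts = {
        "cord": np.cos(2 * np.pi * volume_times / (2 * total) + drift_phase[0]),
        "brain": np.cos(2 * np.pi * volume_times / (2 * total) + drift_phase[1]),
    }

    motion = {
        "brain": MotionParams.from_array(
            np.column_stack(
                [_bounded_walk(rng, T, config.motion_step_mm, 1.0) for _ in range(3)]
                + [_bounded_walk(rng, T, config.motion_step_mm / 50.0, 0.02)
                   for _ in range(3)]
            ),
            "brain",
        ),
        "cord": MotionParams.from_array(
            np.column_stack(
                [_bounded_walk(rng, T, config.motion_step_mm, 1.0) for _ in range(2)]
            ),
            "cord",
        ),
    }

    noise_sd = 0.0 if np.isinf(config.coupling_snr) else 1.0 / config.coupling_snr

    def build_organ(labels_arr, csf, organ):
        grid = labels_arr.shape
        data = np.full(grid + (T,), config.baseline, dtype=float)
        physio = card_v + belt_v
        fd = _fd_power(motion[organ].values, organ)
        common = config.motion_artifact_amplitude * fd + \
            config.drift_amplitude * drifts[organ]
        # shared neural signal per label
        if organ == "cord":
            signals = neural * np.diag(coupling)[:, None]
        else:
            signals = coupling @ neural
        shared_sd = signals.std(axis=1, ddof=0)
        for s in range(1, S + 1):
            vox = labels_arr == s
            n_vox = int(vox.sum())
            if n_vox == 0:
                continue
            sig = signals[s - 1]
            sd = shared_sd[s - 1] * noise_sd
            series = (sig + common + config.physio_amplitude_tissue * physio)[None, :]
            noise = rng.normal(0.0, 1.0, size=(n_vox, T)) * sd if sd > 0 else 0.0
            data[vox] += series + noise
        n_csf = int(csf.sum())
        if n_csf:
            gains = rng.uniform(0.8, 1.2, size=(n_csf, 1))
            csf_series = config.physio_amplitude_csf * gains * physio[None, :]
            csf_series = csf_series + common[None, :]
            csf_series = csf_series + rng.normal(0.0, 0.1, size=(n_csf, T))
            data[csf] += csf_series
        return data

    cord_data = build_organ(cord_labels_arr, cord_csf, "cord")
    brain_data = build_organ(cortex_labels_arr, cortex_csf, "brain")

    cord_affine = np.diag([1.0, 1.0, 3.0, 1.0])
    brain_affine = np.diag([2.0, 2.0, 2.0, 1.0])
    cord = BoldImage(cord_data, tr, cord_affine, "cord")
    brain = BoldImage(brain_data, tr, brain_affine, "brain")
    truth = GroundTruth(
        cord_labels=LabelMap(cord_labels_arr, cord_affine),
        cortex_labels=LabelMap(cortex_labels_arr, brain_affine),
        event_trains=events,
        coupling=coupling,
        csf_masks={"cord": cord_csf, "brain": cortex_csf},
        motion=motion,
        physio=(card, belt),
        neural_signals=neural,
    )
    return brain, cord, truth


def generate_cohort(config: PhantomConfig) -> list[tuple[BoldImage, BoldImage, GroundTruth]]:
    """Generate ``config.n_subjects`` subjects with independent noise.

    Per-subject seeds are derived deterministically from ``rng_seed``;
    the planted geometry (labels, coupling) is identical across subjects
    while events, noise, physiology and motion differ.
    """
    import dataclasses as _dc

    seeds = np.random.SeedSequence(config.rng_seed).generate_state(config.n_subjects)
    return [
        generate_phantom(_dc.replace(config, rng_seed=int(s) % (2**31)))
        for s in seeds
    ]


# ---------------------------------------------------------------------------
# on-disk layout


def write_dataset(
    brain: BoldImage,
    cord: BoldImage,
    truth: GroundTruth,
    directory: str | Path,
    subject: str = "sub-01",
) -> dict:
    """Write one subject to ``directory`` and return a manifest.

    Layout: NIfTI BOLD per organ, NIfTI label maps, TSV motion and
    physio traces, and a JSON ground-truth sidecar.  A round-trip read
    (:func:`read_dataset`) reproduces the arrays exactly.
    """
    from . import io as cio

    directory = Path(directory)
    sub_dir = directory / subject
    try:
        sub_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise FormatError(f"cannot create output directory {sub_dir}: {exc}") from exc

    manifest: dict = {"subject": subject, "images": {}, "motion": {}, "physio": {},
                      "labels": {}}
    for organ, img in (("brain", brain), ("cord", cord)):
        p = sub_dir / f"{subject}_{organ}_bold.nii.gz"
        cio.write_image(img, p)
        manifest["images"][organ] = str(p)
        mp = sub_dir / f"{subject}_{organ}_motion.tsv"
        truth.motion[organ].table.to_csv(mp, sep="\t", index=False)
        manifest["motion"][organ] = str(mp)
    for name, labelmap in (("cord_segments", truth.cord_labels),
                           ("cortex_patches", truth.cortex_labels)):
        p = sub_dir / f"{subject}_{name}.nii.gz"
        cio.write_image(labelmap, p)
        manifest["labels"][name] = str(p)
    for trace in truth.physio:
        p = sub_dir / f"{subject}_{trace.modality}.tsv"
        df = pd.DataFrame({"time_s": trace.times, "amplitude": trace.samples})
        df.to_csv(p, sep="\t", index=False)
        manifest["physio"][trace.modality] = str(p)

    truth_path = sub_dir / f"{subject}_truth.json"
    sidecar = {
        "event_trains": truth.event_trains.tolist(),
        "coupling": truth.coupling.tolist(),
        "cardiac_peak_times_s": truth.physio[0].peak_times_seconds.tolist(),
        "physio_sampling_rate_hz": truth.physio[0].sampling_rate_hz,
        "csf_masks": {k: np.asarray(v, dtype=int).tolist()
                      for k, v in truth.csf_masks.items()},
    }
    truth_path.write_text(json.dumps(sidecar))
    manifest["truth"] = str(truth_path)

    manifest_path = sub_dir / f"{subject}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest["manifest"] = str(manifest_path)
    return manifest


def read_dataset(manifest: dict) -> tuple[BoldImage, BoldImage, GroundTruth]:
    """Read a subject back from a :func:`write_dataset` manifest."""
    from . import io as cio

    brain = cio.read_image(manifest["images"]["brain"])
    cord = cio.read_image(manifest["images"]["cord"])
    cord_labels = cio.read_image(manifest["labels"]["cord_segments"])
    cortex_labels = cio.read_image(manifest["labels"]["cortex_patches"])
    sidecar = json.loads(Path(manifest["truth"]).read_text())
    motion = {}
    for organ in ("brain", "cord"):
        df = pd.read_csv(manifest["motion"][organ], sep="\t")
        motion[organ] = MotionParams(df)
    physio = []
    for modality in ("cardiac", "respiratory"):
        df = pd.read_csv(manifest["physio"][modality], sep="\t")
        peaks = (np.asarray(sidecar["cardiac_peak_times_s"])
                 if modality == "cardiac" else None)
        physio.append(
            PhysioTrace(df["amplitude"].to_numpy(),
                        sidecar["physio_sampling_rate_hz"], modality, peaks)
        )
    truth = GroundTruth(
        cord_labels=cord_labels,
        cortex_labels=cortex_labels,
        event_trains=np.asarray(sidecar["event_trains"], dtype=float),
        coupling=np.asarray(sidecar["coupling"], dtype=float),
        csf_masks={k: np.asarray(v, dtype=bool)
                   for k, v in sidecar["csf_masks"].items()},
        motion=motion,
        physio=tuple(physio),
    )
    return brain, cord, truth


def config_to_dict(config: PhantomConfig) -> dict:
    d = asdict(config)
    d["cord_grid"] = list(d["cord_grid"])
    d["cortex_grid"] = list(d["cortex_grid"])
    return d
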