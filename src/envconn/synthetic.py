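"""Synthetic two-group cohort generator.

Emulates, at desk scale, the statistical structure of a source-space MEG
resting-state study of multiple sclerosis: band-limited oscillatory node
signals whose slow amplitude envelopes carry a prescribed correlation
structure within and across frequency bands, group-specific connectivity
reductions, behavioral scores linearly coupled to selected connections,
demographic/technical confounds, and two structural damage markers (lesion
load, normalized thalamic volume) partially coupled to cognition.

Generative model, per subject
-----------------------------
Each (node, band) entry k gets a signal  x_k(t) = c_k(t) * e_k(t):

* ``c_k`` — carrier: unit-variance white noise band-passed into the entry's
  band (realistic bandwidth; not a pure tone).
* ``e_k`` — envelope: ``exp(sigma_log * z_k)`` where the ``z_k`` are
  standardized low-pass (<= 1 Hz) Gaussian processes correlated across
  entries by the Cholesky factor of a latent correlation matrix.
  Exponentiation guarantees strict positivity; sharing latent factors
  across bands is what makes cross-frequency envelope coupling plantable.

``target_corr`` is expressed on the scale the analysis pipeline measures:
the Pearson correlation between slow Hilbert envelopes.  Two known
attenuations separate that scale from the latent Gaussian one, and the
generator inverts both analytically (see :func:`latent_from_target`):

1. lognormal compression — two exponentiated Gaussians with correlation
   ``rho`` have Pearson correlation ``(exp(s*rho)-1)/(exp(s)-1)`` with
   ``s = sigma_log**2``;
2. carrier dilution — the measured envelope is (to first order) the product
   of the planted envelope and the slow residue of the carrier's own
   Rayleigh envelope, an independent multiplicative noise whose squared
   coefficient of variation ``c_b`` is estimated once per band by filtering
   a long white-noise realization through the analysis envelope chain.

Targets above the per-band feasibility limit (perfect latent correlation)
are clipped and reported in the ground-truth record.

If a leakage mixing matrix is supplied, the per-node broadband sums are
mixed instantaneously across nodes and re-filtered into bands, reproducing
the zero-lag correlation inflation that pairwise orthogonalization is meant
to remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .connectome import (
    BandSignalSet,
    DEFAULT_ENVELOPE_CUTOFF_HZ,
    FILTER_ORDER,
    fast_slow_envelope,
)
from .parcellation import BandDef, ConnectomeDef, NodeDef

#: Neuropsychological battery (7 scores) plus depression; EDSS and disease
#: duration exist for patients only.
NEUROPSYCH_SCORES = (
    "SDMT", "CVLT", "BVMT_R", "COWAT", "FSMC_motor", "FSMC_cognitive", "NHPT",
)
BEHAVIORAL_SCORES = NEUROPSYCH_SCORES + ("BDI",)
PATIENT_ONLY_SCORES = ("EDSS", "disease_duration")
ALL_SCORES = BEHAVIORAL_SCORES + PATIENT_ONLY_SCORES

CONFOUND_COLUMNS = ("age", "sex", "education", "system", "benzodiazepine")


class CohortSpecError(ValueError):
    """Invalid cohort specification."""


# ---------------------------------------------------------------------------
# Spec dataclasses

@dataclass
class GroupEffect:
    """Additive change of one envelope correlation in the patient group."""

    node_i: int
    band_a: int
    node_j: int
    band_b: int
    delta: float


@dataclass
class BehaviorCoupling:
    """One connection's contribution to a behavioral score."""

    score: str
    node_i: int
    band_a: int
    node_j: int
    band_b: int
    weight: float


@dataclass
class StructuralModel:
    """Distributions of the two structural markers and their couplings.

    Lesion load is in millilitres (gamma-distributed, patients carry
    substantial load, controls essentially none); thalamic volume is
    normalized to intracranial volume (percent, roughly Gaussian, reduced
    in patients).  ``score_weights`` maps a score name to the pair
    (weight on standardized lesion load, weight on standardized thalamic
    volume) added to patients' scores.
    """

    lesion_mean_patient: float = 10.0
    lesion_shape_patient: float = 1.5
    lesion_mean_control: float = 0.3
    lesion_shape_control: float = 1.0
    thalamus_mean_patient: float = 0.82
    thalamus_mean_control: float = 0.92
    thalamus_sd: float = 0.07
    score_weights: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class CohortSpec:
    """Everything needed to generate one two-group cohort."""

    conn: ConnectomeDef
    n_group_a: int = 20  # patients
    n_group_b: int = 20  # controls
    sampling_rate: float = 250.0
    duration: float = 60.0
    target_corr: np.ndarray | None = None  # control-group (E x E), measured scale
    group_effects: list[GroupEffect] = field(default_factory=list)
    behavior_couplings: list[BehaviorCoupling] = field(default_factory=list)
    behavior_noise_sd: float = 1.0
    confound_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    subject_corr_sd: float = 0.15  # subject-level jitter of coupled connections
    leakage_mix: np.ndarray | None = None
    structural: StructuralModel = field(default_factory=StructuralModel)
    sigma_log: float = 0.7  # SD of the log-envelope fluctuations
    envelope_cutoff_hz: float = 0.5  # latent envelope bandwidth
    analysis_cutoff_hz: float = DEFAULT_ENVELOPE_CUTOFF_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        E = self.conn.n_entries
        if self.target_corr is None:
            self.target_corr = np.eye(E)
        self.target_corr = np.asarray(self.target_corr, dtype=float)
        if self.target_corr.shape != (E, E):
            raise CohortSpecError(
                f"target_corr must be {E}x{E} over (node, band) entries"
            )
        if not np.allclose(self.target_corr, self.target_corr.T):
            raise CohortSpecError("target_corr must be symmetric")
        if not np.allclose(np.diag(self.target_corr), 1.0):
            raise CohortSpecError("target_corr must have unit diagonal")
        if np.linalg.eigvalsh(self.target_corr).min() < -1e-10:
            raise CohortSpecError("target_corr must be positive semidefinite")
        if self.duration <= 0:
            raise CohortSpecError("duration must be positive")
        top = max(b.high_hz for b in self.conn.bands)
        if self.sampling_rate <= 2 * top:
            raise CohortSpecError(
                f"sampling_rate {self.sampling_rate} Hz too low for the top "
                f"band edge {top} Hz"
            )
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise CohortSpecError("need at least 2 subjects per group")
        if self.leakage_mix is not None:
            self.leakage_mix = np.asarray(self.leakage_mix, dtype=float)
            n = self.conn.n_nodes
            if self.leakage_mix.shape != (n, n):
                raise CohortSpecError(f"leakage_mix must be {n}x{n}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    target_corr_control: np.ndarray
    target_corr_patient: np.ndarray
    clipped_entries: list[tuple[int, int]]
    carrier_cv2: np.ndarray  # per band
    subject_true_corr: dict[str, dict[str, float]]  # subject -> "p,q" -> r
    seed: int


# ---------------------------------------------------------------------------
# Latent-scale calibration

@lru_cache(maxsize=64)
def _carrier_gain(low: float, high: float, fs: float, n_samples: int
                  ) -> np.ndarray:
    """Zero-phase band-pass amplitude response on the rfft frequency grid."""
    from scipy.signal import sosfreqz

    sos = butter(FILTER_ORDER, [low, high], btype="bandpass", fs=fs,
                 output="sos")
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    _, H = sosfreqz(sos, worN=2 * np.pi * freqs / fs)
    return np.abs(H) ** 2  # forward-backward filtering squares |H|


def _make_carriers(rng: np.random.Generator, n_rows: int, n_samples: int,
                   band: BandDef, fs: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise rows.

    Synthesized spectrally: white complex Gaussian coefficients shaped by
    the zero-phase band-pass amplitude response, then inverse-transformed —
    statistically equivalent to filtering white noise, at a fraction of the
    cost.
    """
    gain = _carrier_gain(band.low_hz, band.high_hz, fs, n_samples)
    nf = gain.size
    F = (rng.standard_normal((n_rows, nf)) +
         1j * rng.standard_normal((n_rows, nf))) * gain
    x = np.fft.irfft(F, n=n_samples, axis=-1)
    sd = np.maximum(x.std(axis=-1, keepdims=True), np.finfo(float).tiny)
    return x / sd


@lru_cache(maxsize=64)
def _carrier_cv2_cached(low: float, high: float, fs: float, cutoff: float,
                        calib_duration: float) -> float:
    rng = np.random.default_rng(1234567)
    T = int(calib_duration * fs)
    x = _make_carriers(rng, 4, T, BandDef("calib", low, high), fs)
    slow, _, trim = fast_slow_envelope(x, fs, cutoff)
    slow = slow[:, trim:-trim]
    return float(np.var(slow) / np.mean(slow) ** 2)


def carrier_envelope_cv2(
    band: BandDef,
    sampling_rate: float,
    analysis_cutoff_hz: float = DEFAULT_ENVELOPE_CUTOFF_HZ,
    calib_duration: float = 300.0,
) -> float:
    """Squared coefficient of variation of the slow carrier envelope.

    Band-passed unit white noise is pushed through the same envelope chain
    the analysis uses (analytic magnitude, decimation, low-pass, edge
    trim); the returned CV^2 quantifies the multiplicative envelope noise
    the carrier contributes to any measured envelope correlation.  Uses a
    fixed internal seed and is cached: this is a population constant of the
    (band, fs, cutoff) triple, not a random quantity.
    """
    return _carrier_cv2_cached(band.low_hz, band.high_hz, sampling_rate,
                               analysis_cutoff_hz, calib_duration)


def latent_from_target(
    target: np.ndarray,
    sigma_log: float,
    cv2_by_entry: np.ndarray,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Map measured-scale envelope correlations to latent Gaussian ones.

    Inverts ``r = (exp(s*rho) - 1) / sqrt(D_p * D_q)`` where
    ``D_k = exp(s)*(1 + c_k) - 1`` is the total variance factor of entry k's
    measured envelope (lognormal fluctuation plus carrier dilution ``c_k``).
    Entries whose target exceeds the feasible maximum (``rho = 1``) are
    clipped and reported.
    """
    s = sigma_log**2
    D = np.exp(s) * (1.0 + cv2_by_entry) - 1.0
    denom = np.sqrt(np.outer(D, D))
    arg = 1.0 + target * denom
    clipped: list[tuple[int, int]] = []
    rho = np.log(np.maximum(arg, np.exp(-s) * 0.999)) / s
    over = rho > 1.0
    if np.any(over):
        iu, ju = np.where(np.triu(over, k=1))
        clipped = list(zip(iu.tolist(), ju.tolist()))
        rho = np.minimum(rho, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho, clipped


def _psd_repair(C: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Clip tiny negative eigenvalues and restore the unit diagonal."""
    w, V = np.linalg.eigh((C + C.T) / 2)
    if w.min() >= floor:
        return C
    w = np.maximum(w, floor)
    R = (V * w) @ V.T
    d = np.sqrt(np.diag(R))
    return R / np.outer(d, d)


# ---------------------------------------------------------------------------
# Signal synthesis

def _synth_signals(
    spec: CohortSpec,
    chol: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One subject's nodes x bands x samples array from a latent Cholesky
    factor over (node, band) entries."""
    conn = spec.conn
    n, nb, T = conn.n_nodes, conn.n_bands, spec.n_samples
    E = n * nb
    fs = spec.sampling_rate

    # Correlated slow Gaussian log-envelopes, unit marginal variance.
    # Generated at a low rate (the latent process is band-limited to the
    # envelope cutoff) and linearly interpolated up to the signal rate.
    dec = max(1, int(fs // (20.0 * spec.envelope_cutoff_hz)))
    fs_lat = fs / dec
    Tl = T // dec + 2
    W = rng.standard_normal((E, Tl))
    sos_env = butter(FILTER_ORDER, spec.envelope_cutoff_hz, btype="lowpass",
                     fs=fs_lat, output="sos")
    Z = sosfiltfilt(sos_env, chol @ W, axis=-1)
    Z /= np.maximum(Z.std(axis=-1, keepdims=True), np.finfo(float).tiny)
    if dec > 1:
        t_full = np.arange(T) / fs
        t_lat = np.arange(Tl) * dec / fs
        Z = np.stack([np.interp(t_full, t_lat, z) for z in Z])
    env = np.exp(spec.sigma_log * Z)

    # Independent band-passed carriers, unit variance.
    C = np.empty((E, T))
    for b, band in enumerate(conn.bands):
        idx = slice(b, E, nb)  # node-major, band-minor flat order
        C[idx] = _make_carriers(rng, n, T, band, fs)

    X = (C * env).reshape(n, nb, T)

    if spec.leakage_mix is not None:
        broadband = X.sum(axis=1)  # nodes x T
        mixed = spec.leakage_mix @ broadband
        X = np.empty((n, nb, T))
        for b, band in enumerate(conn.bands):
            sos_b = butter(FILTER_ORDER, [band.low_hz, band.high_hz],
                           btype="bandpass", fs=fs, output="sos")
            X[:, b, :] = sosfiltfilt(sos_b, mixed, axis=-1)
    return X


def _patient_target(spec: CohortSpec) -> np.ndarray:
    """Control-group target with the planted group effects applied."""
    M = spec.target_corr.copy()
    for ge in spec.group_effects:
        p = spec.conn.flat_index(ge.node_i, ge.band_a)
        q = spec.conn.flat_index(ge.node_j, ge.band_b)
        M[p, q] += ge.delta
        M[q, p] += ge.delta
    if np.any(np.abs(M - np.diag(np.diag(M))) >= 1.0):
        raise CohortSpecError("group effect pushes a correlation out of (-1, 1)")
    if np.linalg.eigvalsh(M).min() < -1e-10:
        raise CohortSpecError("patient target correlation is not PSD")
    return M


# ---------------------------------------------------------------------------
# Cohort generation

def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[BandSignalSet], pd.DataFrame, GroundTruth]:
    """Generate signals, subject table and ground truth for one cohort.

    Deterministic given ``spec.seed``.  Group A subjects are patients,
    group B healthy controls; subject ids are ``P000.., C000..``.
    """
    conn = spec.conn
    rng = np.random.default_rng(spec.seed)
    E = conn.n_entries

    cv2_band = np.array([
        carrier_envelope_cv2(b, spec.sampling_rate, spec.analysis_cutoff_hz)
        for b in conn.bands
    ])
    cv2_entry = np.tile(cv2_band, conn.n_nodes)

    target_c = spec.target_corr
    target_p = _patient_target(spec)

    coupled = sorted({
        tuple(sorted((conn.flat_index(bc.node_i, bc.band_a),
                      conn.flat_index(bc.node_j, bc.band_b))))
        for bc in spec.behavior_couplings
    })

    def latent_chol(target: np.ndarray) -> tuple[np.ndarray, list]:
        rho, clipped = latent_from_target(target, spec.sigma_log, cv2_entry)
        rho = _psd_repair(rho)
        return np.linalg.cholesky(rho + 1e-12 * np.eye(E)), clipped

    chol_c, clip_c = latent_chol(target_c)
    chol_p, clip_p = latent_chol(target_p)

    signals: list[BandSignalSet] = []
    rows: list[dict] = []
    subject_true: dict[str, dict[str, float]] = {}

    groups = [("patient", spec.n_group_a, target_p, chol_p),
              ("control", spec.n_group_b, target_c, chol_c)]
    for gname, count, gtarget, gchol in groups:
        for k in range(count):
            sid = ("P" if gname == "patient" else "C") + f"{k:03d}"
            # Subject-level true correlations: jitter the coupled entries.
            true_vals: dict[str, float] = {}
            if coupled:
                tgt = gtarget.copy()
                for (p, q) in coupled:
                    r = float(np.clip(
                        gtarget[p, q] + spec.subject_corr_sd * rng.standard_normal(),
                        -0.85, 0.85,
                    ))
                    tgt[p, q] = tgt[q, p] = r
                    true_vals[f"{p},{q}"] = r
                chol, _ = latent_chol(tgt)
            else:
                chol = gchol
            X = _synth_signals(spec, chol, rng)
            signals.append(BandSignalSet(X, spec.sampling_rate, subject_id=sid))
            subject_true[sid] = true_vals
            rows.append(_subject_row(sid, gname, true_vals, spec, rng))

    table = pd.DataFrame(rows)
    truth = GroundTruth(
        target_corr_control=target_c,
        target_corr_patient=target_p,
        clipped_entries=sorted(set(clip_c) | set(clip_p)),
        carrier_cv2=cv2_band,
        subject_true_corr=subject_true,
        seed=spec.seed,
    )
    return signals, table, truth


def _subject_row(
    sid: str,
    group: str,
    true_vals: dict[str, float],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> dict:
    is_patient = group == "patient"
    sm = spec.structural
    row: dict = {
        "subject": sid,
        "group": group,
        "age": float(rng.normal(48.0, 10.0)),
        "sex": int(rng.integers(0, 2)),
        "education": float(rng.normal(14.0, 3.0)),
        "system": int(rng.integers(0, 2)),
        "benzodiazepine": int(rng.integers(0, 2)) if is_patient else 0,
    }
    if is_patient:
        mean, shape = sm.lesion_mean_patient, sm.lesion_shape_patient
        thal_mean = sm.thalamus_mean_patient
    else:
        mean, shape = sm.lesion_mean_control, sm.lesion_shape_control
        thal_mean = sm.thalamus_mean_control
    row["lesion_load"] = float(rng.gamma(shape, mean / shape))
    row["thalamic_volume"] = float(
        np.clip(rng.normal(thal_mean, sm.thalamus_sd), 1e-3, None)
    )

    lesion_z = (row["lesion_load"] - mean) / max(mean, 1e-9)
    thal_z = (row["thalamic_volume"] - thal_mean) / sm.thalamus_sd

    for score in ALL_SCORES:
        if score in PATIENT_ONLY_SCORES and not is_patient:
            row[score] = np.nan
            continue
        val = 0.0
        for bc in spec.behavior_couplings:
            if bc.score != score:
                continue
            p = spec.conn.flat_index(bc.node_i, bc.band_a)
            q = spec.conn.flat_index(bc.node_j, bc.band_b)
            key = f"{min(p, q)},{max(p, q)}"
            val += bc.weight * true_vals.get(key, 0.0)
        for conf, w in spec.confound_weights.get(score, {}).items():
            val += w * row[conf]
        if is_patient and score in sm.score_weights:
            wl, wt = sm.score_weights[score]
            val += wl * lesion_z + wt * thal_z
        row[score] = val + spec.behavior_noise_sd * float(rng.standard_normal())
    return row


def generate_null_cohort(
    n_a: int,
    n_b: int,
    conn: ConnectomeDef,
    seed: int,
    target_corr: np.ndarray | None = None,
    **kwargs,
) -> tuple[list[BandSignalSet], pd.DataFrame, GroundTruth]:
    """Two groups drawn from one shared envelope-correlation model.

    No group effect, no behavior coupling: the exchangeable null for
    family-wise error calibration.
    """
    spec = CohortSpec(
        conn=conn, n_group_a=n_a, n_group_b=n_b,
        target_corr=target_corr, seed=seed, **kwargs,
    )
    return generate_cohort(spec)


# ---------------------------------------------------------------------------
# Reference correlation structures

def default_target_corr(
    conn: ConnectomeDef,
    within_network_r: float = 0.3,
    cross_network_r: float = 0.1,
    cross_band_scale: float = 0.5,
) -> np.ndarray:
    """A realistic resting-state-like target: elevated within-network
    coupling, weak cross-network coupling, cross-band couplings scaled
    down; entries between a node's own bands follow the same rule."""
    E = conn.n_entries
    M = np.eye(E)
    for p in range(E):
        i, a = conn.unflatten(p)
        for q in range(p + 1, E):
            j, b = conn.unflatten(q)
            if i == j:
                r = within_network_r  # same node across bands
            elif conn.nodes[i].network == conn.nodes[j].network:
                r = within_network_r
            else:
                r = cross_network_r
            if a != b:
                r *= cross_band_scale
            M[p, q] = M[q, p] = r
    return _psd_repair(M)


def toy_connectome(n_nodes: int = 10, n_bands: int = 2) -> ConnectomeDef:
    """Small desk-scale parcellation: nodes alternate over two networks
    (or more for larger n), bands taken from the canonical five."""
    from .parcellation import NETWORKS, default_bands

    n_nets = 2 if n_nodes <= 12 else 3
    nodes = tuple(
        NodeDef(f"N{i:02d}", NETWORKS[i % n_nets], "L" if i % 2 == 0 else "R")
        for i in range(n_nodes)
    )
    bands = default_bands()[2:2 + n_bands]  # alpha up: decent bandwidths
    if len(bands) < n_bands:
        bands = default_bands()[-n_bands:]
    return ConnectomeDef(nodes, bands)


# ---------------------------------------------------------------------------
# Persistence (HDF5 signals, CSV table, JSON ground truth)

def save_cohort(
    out_dir: str | Path,
    signals: list[BandSignalSet],
    table: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "signals.h5", "w") as f:
        for s in signals:
            d = f.create_dataset(s.subject_id, data=s.values)
            d.attrs["sampling_rate"] = s.sampling_rate
    table.to_csv(out / "subjects.csv", index=False)
    if truth is not None:
        payload = {
            "seed": truth.seed,
            "carrier_cv2": truth.carrier_cv2.tolist(),
            "clipped_entries": truth.clipped_entries,
            "target_corr_control": truth.target_corr_control.tolist(),
            "target_corr_patient": truth.target_corr_patient.tolist(),
            "subject_true_corr": truth.subject_true_corr,
        }
        (out / "ground_truth.json").write_text(json.dumps(payload, indent=1))


def load_cohort(out_dir: str | Path) -> tuple[list[BandSignalSet], pd.DataFrame]:
    out = Path(out_dir)
    signals = []
    with h5py.File(out / "signals.h5", "r") as f:
        for sid in sorted(f.keys()):
            signals.append(
                BandSignalSet(f[sid][()], float(f[sid].attrs["sampling_rate"]),
                              subject_id=sid)
            )
    table = pd.read_csv(out / "subjects.csv")
    return signals, table
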