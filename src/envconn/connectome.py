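"""Band-limited power-envelope correlation connectomics.

Pipeline, per subject: band-pass filter the node time series into the
analysis bands; reduce spatial leakage by pairwise static orthogonalization
(removing from one node's signal its zero-lag projection onto the other's);
extract the slow amplitude envelope (Hilbert magnitude, low-pass filtered to
1 Hz); Pearson-correlate envelopes over all node pairs and all band pairs to
form a symmetric multi-layer (node, band) x (node, band) connectivity
matrix; and aggregate it into mean within- and cross-network couplings.

Conventions fixed here (the upstream description leaves them open):

* Filters are zero-phase (forward-backward 4th-order Butterworth), so group
  delay never misaligns envelopes.
* Leakage is instantaneous and band-preserving, so for a cross-frequency
  entry (node i, band a) x (node j, band b) the orthogonalization is done
  within each node's own band: j's band-b signal is orthogonalized against
  i's band-b signal before envelope extraction (and symmetrically for the
  reverse direction); the two directions are averaged.
* One low-pass filter length (1/cutoff seconds) is trimmed from both ends
  of every envelope before correlating, removing Hilbert/filter transients.
* Envelopes are correlated raw — no log transform or Fisher z here.
* Same-node entries (all band pairs) are undefined: they are confounded by
  shared broadband amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.fft as sfft
from scipy.signal import butter, hilbert, sosfiltfilt

from .parcellation import BandDef, ConnectomeDef

#: Residual variance below this fraction of the original variance flags a
#: connection as undefined (collinearity guard).
COLLINEARITY_TOL = 1e-12

DEFAULT_ENVELOPE_CUTOFF_HZ = 1.0
FILTER_ORDER = 4


class SignalError(ValueError):
    """Invalid signal input (sampling, dimensions, degeneracy)."""


# ---------------------------------------------------------------------------
# Containers

@dataclass
class BandSignalSet:
    """Per-subject band-limited node signals: nodes x bands x samples."""

    values: np.ndarray
    sampling_rate: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise SignalError(
                f"expected nodes x bands x samples, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise SignalError("non-finite samples in signal set")
        if self.sampling_rate <= 0:
            raise SignalError("sampling_rate must be positive")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]


@dataclass
class PowerEstimate:
    """Noise-standardized absolute power (temporal variance) per node/band."""

    values: np.ndarray  # nodes x bands, >= 0
    standardized: bool = True


@dataclass
class MultiLayerRSFC:
    """Symmetric (node, band) x (node, band) envelope-correlation matrix.

    ``values`` is indexed node-major / band-minor on both axes; ``defined``
    masks valid entries (same-node blocks and collinear pairs are False,
    with NaN in ``values``).
    """

    values: np.ndarray
    defined: np.ndarray
    conn: ConnectomeDef
    power: PowerEstimate | None = None

    def entry(self, node_i: int, band_a: int, node_j: int, band_b: int) -> float:
        return float(
            self.values[self.conn.flat_index(node_i, band_a),
                        self.conn.flat_index(node_j, band_b)]
        )


@dataclass
class MeanNetworkRSFC:
    """Mean within-/cross-network couplings per band pair.

    ``values[p, q]`` with p=(network u, band a), q=(network v, band b) is
    the arithmetic mean of the defined multi-layer entries over qualifying
    node pairs; ``counts`` stores how many entries contributed.
    """

    values: np.ndarray
    counts: np.ndarray
    networks: tuple[str, ...]
    conn: ConnectomeDef
    network_power: np.ndarray | None = None  # networks x bands

    def entry(self, net_u: str, band_a: int, net_v: str, band_b: int) -> float:
        nb = self.conn.n_bands
        p = self.networks.index(net_u) * nb + band_a
        q = self.networks.index(net_v) * nb + band_b
        return float(self.values[p, q])


# ---------------------------------------------------------------------------
# Filtering primitives

@lru_cache(maxsize=256)
def _sos_cached(edges: tuple[float, ...], btype: str, fs: float):
    return butter(FILTER_ORDER, list(edges) if len(edges) > 1 else edges[0],
                  btype=btype, fs=fs, output="sos")


def _bandpass_sos(band: BandDef, fs: float):
    return _sos_cached((band.low_hz, band.high_hz), "bandpass", fs)


def _lowpass_sos(cutoff_hz: float, fs: float):
    return _sos_cached((cutoff_hz,), "lowpass", fs)


def bandpass(signals: np.ndarray, band: BandDef, sampling_rate: float) -> np.ndarray:
    """Zero-phase band-pass along the last axis; output length = input length.

    Raises if the band's upper edge reaches the Nyquist frequency.
    """
    if band.high_hz >= sampling_rate / 2:
        raise SignalError(
            f"band {band.name!r} upper edge {band.high_hz} Hz at or above "
            f"Nyquist ({sampling_rate / 2} Hz)"
        )
    x = np.asarray(signals, dtype=float)
    return sosfiltfilt(_bandpass_sos(band, sampling_rate), x, axis=-1)


def envelope_edge_samples(sampling_rate: float,
                          cutoff_hz: float = DEFAULT_ENVELOPE_CUTOFF_HZ) -> int:
    """Samples to trim at each envelope end: one low-pass filter length."""
    return int(round(sampling_rate / cutoff_hz))


def slow_envelope(
    band_signal: np.ndarray,
    sampling_rate: float,
    cutoff_hz: float = DEFAULT_ENVELOPE_CUTOFF_HZ,
    band: BandDef | None = None,
) -> np.ndarray:
    """Slow amplitude envelope: |analytic signal| low-passed at ``cutoff_hz``.

    Operates along the last axis.  If ``band`` is given, a cutoff at or
    above the band's low edge is rejected (the envelope would overlap the
    carrier).  The first/last :func:`envelope_edge_samples` samples contain
    filter transients; callers correlate interior samples only.
    """
    if band is not None and cutoff_hz >= band.low_hz:
        raise SignalError(
            f"envelope cutoff {cutoff_hz} Hz must lie below the band low "
            f"edge {band.low_hz} Hz"
        )
    x = np.asarray(band_signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise SignalError("non-finite samples")
    env = np.abs(hilbert(x, axis=-1))
    return sosfiltfilt(_lowpass_sos(cutoff_hz, sampling_rate), env, axis=-1)


#: Decimation keeps the envelope sample rate at ~10x the low-pass cutoff.
ENVELOPE_OVERSAMPLING = 10.0


def _decimation_factor(sampling_rate: float, cutoff_hz: float) -> int:
    return max(1, int(sampling_rate // (ENVELOPE_OVERSAMPLING * cutoff_hz)))


def fast_slow_envelope(
    x: np.ndarray,
    sampling_rate: float,
    cutoff_hz: float = DEFAULT_ENVELOPE_CUTOFF_HZ,
) -> tuple[np.ndarray, float, int]:
    """Batched slow envelope on a decimated time axis.

    Computes the analytic-signal magnitude along the last axis (single-
    precision rfft — envelopes enter correlations, where 1e-7 relative
    accuracy is far below statistical noise), average-pools it down to
    roughly ``ENVELOPE_OVERSAMPLING x cutoff_hz``, then zero-phase low-pass
    filters at ``cutoff_hz``.  Returns ``(envelope, envelope_rate,
    edge_samples)`` where ``edge_samples`` is the transient length (one
    filter length, 1/cutoff seconds) to trim from each end before use.

    This is the estimator the connectome builders use; :func:`slow_envelope`
    is its exact full-rate counterpart for single signals.
    """
    x32 = np.ascontiguousarray(x, dtype=np.float32)
    T = x32.shape[-1]
    F = sfft.rfft(x32, axis=-1)
    h = np.full(F.shape[-1], 2.0, dtype=np.float32)
    h[0] = 1.0
    if T % 2 == 0:
        h[-1] = 1.0
    spec = np.zeros(x32.shape[:-1] + (T,), dtype=np.complex64)
    spec[..., : F.shape[-1]] = F * h
    env = np.abs(sfft.ifft(spec, axis=-1))
    d = _decimation_factor(sampling_rate, cutoff_hz)
    if d > 1:
        Td = T // d
        env = env[..., : Td * d].reshape(env.shape[:-1] + (Td, d)).mean(-1)
    fs_env = sampling_rate / d
    env = sosfiltfilt(_lowpass_sos(cutoff_hz, fs_env),
                      env.astype(np.float64), axis=-1)
    return env, fs_env, int(round(fs_env / cutoff_hz))


def orthogonalize_static(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Remove from ``y`` its zero-lag projection onto ``x``.

    Returns ``y - (<x,y>/<x,x>) x``, which has zero inner product with ``x``.
    Raises if ``x`` is identically zero.  Callers must treat a residual with
    near-zero variance (collinear pair) as an undefined connection.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xx = float(x @ x)
    if xx == 0.0:
        raise SignalError("cannot orthogonalize against an all-zero signal")
    return y - (float(x @ y) / xx) * x


def node_power(band_signal: np.ndarray, noise_variance: float = 1.0) -> float:
    """Absolute power (temporal variance) standardized by the noise variance."""
    if noise_variance <= 0:
        raise SignalError("noise_variance must be positive")
    return float(np.var(np.asarray(band_signal, dtype=float))) / noise_variance


def power_estimate(subject: BandSignalSet,
                   noise_variance: float | np.ndarray = 1.0) -> PowerEstimate:
    """Node x band noise-standardized power for one subject."""
    nv = np.broadcast_to(np.asarray(noise_variance, dtype=float),
                         subject.values.shape[:2])
    if np.any(nv <= 0):
        raise SignalError("noise_variance must be positive")
    return PowerEstimate(np.var(subject.values, axis=-1) / nv, standardized=True)


# ---------------------------------------------------------------------------
# Pairwise connectivity

def _corr_interior(a: np.ndarray, b: np.ndarray, trim: int) -> float:
    a = a[..., trim:-trim] if trim else a
    b = b[..., trim:-trim] if trim else b
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def pair_rsfc(
    sig_i: np.ndarray,
    sig_j: np.ndarray,
    sampling_rate: float,
    orthogonalize: bool = True,
    cutoff_hz: float = DEFAULT_ENVELOPE_CUTOFF_HZ,
) -> float:
    """Envelope correlation between two nodes' band signals.

    ``sig_i`` and ``sig_j`` each have shape (2, samples): row 0 is the
    node's signal in the *entry* band (the band whose envelope enters the
    correlation), row 1 the node's signal in the *other node's* entry band
    (the band in which leakage removal happens).  For a within-frequency
    entry pass the same signal twice.

    For the entry ((i, a), (j, b)): direction 1 orthogonalizes node j's
    band-b signal against node i's band-b signal and correlates the
    residual's envelope with node i's band-a envelope; direction 2 is the
    mirror image (i's band-a signal cleaned against j's band-a signal,
    correlated with j's band-b envelope).  The two directions are
    averaged.  Returns NaN when a residual is collinear (undefined
    connection).
    """
    ei_a, ei_b = np.asarray(sig_i, float)
    ej_b, ej_a = np.asarray(sig_j, float)

    def one_direction(ref_env_src: np.ndarray, other_same_band: np.ndarray,
                      ref_same_band: np.ndarray) -> float:
        # ref node's envelope in its entry band vs the other node's
        # leakage-cleaned envelope in its own entry band.
        if orthogonalize:
            resid = orthogonalize_static(ref_same_band, other_same_band)
            if np.var(resid) < COLLINEARITY_TOL * max(np.var(other_same_band),
                                                      np.finfo(float).tiny):
                return np.nan
        else:
            resid = other_same_band
        envs, _, trim = fast_slow_envelope(
            np.vstack([ref_env_src, resid]), sampling_rate, cutoff_hz)
        return _corr_interior(envs[0], envs[1], trim)

    # direction 1: i is reference; j's entry-band (b) signal cleaned
    # against i's band-b signal
    r1 = one_direction(ei_a, ej_b, ei_b)
    # direction 2: j is reference; i's entry-band (a) signal cleaned
    # against j's band-a signal
    r2 = one_direction(ej_b, ei_a, ej_a)
    if np.isnan(r1) or np.isnan(r2):
        return np.nan
    return 0.5 * (r1 + r2)


def build_multilayer(
    subject: BandSignalSet,
    conn: ConnectomeDef,
    orthogonalize: bool = True,
    cutoff_hz: float = DEFAULT_ENVELOPE_CUTOFF_HZ,
    noise_variance: float | np.ndarray = 1.0,
) -> MultiLayerRSFC:
    """Full multi-layer rsFC matrix for one subject.

    Vectorized equivalent of running :func:`pair_rsfc` over every node pair
    and band pair: all ordered-pair residuals are formed per band with one
    matrix operation, enveloped in one batched Hilbert/low-pass call, and
    correlated with the raw reference envelopes.
    """
    if subject.n_nodes != conn.n_nodes:
        raise SignalError(
            f"signal has {subject.n_nodes} nodes, connectome {conn.n_nodes}"
        )
    if subject.n_bands != conn.n_bands:
        raise SignalError(
            f"signal has {subject.n_bands} bands, connectome {conn.n_bands}"
        )
    for b in conn.bands:
        if cutoff_hz >= b.low_hz:
            raise SignalError(
                f"envelope cutoff {cutoff_hz} Hz overlaps band {b.name!r}"
            )
    X = subject.values
    n, nb, T = X.shape
    fs = subject.sampling_rate

    def env_trimmed(sig: np.ndarray) -> np.ndarray:
        e, _, trim = fast_slow_envelope(sig, fs, cutoff_hz)
        if e.shape[-1] <= 2 * trim + 2:
            raise SignalError("recording too short for envelope edge trimming")
        return e[..., trim:e.shape[-1] - trim]

    def zscore(e: np.ndarray) -> np.ndarray:
        mu = e.mean(axis=-1, keepdims=True)
        sd = e.std(axis=-1, keepdims=True)
        return (e - mu) / np.where(sd == 0, np.nan, sd)

    env_raw = zscore(env_trimmed(X))  # nodes x bands x T'
    Tp = env_raw.shape[-1]

    # Per-band Gram matrices give both the orthogonalization coefficients
    # and the residual variances (collinearity guard) without touching the
    # full-length residual arrays again.
    r1 = np.empty((n, nb, n, nb))
    res_ok = np.ones((n, n, nb), dtype=bool)  # [ref i, other j, band b]
    if orthogonalize:
        gram, mean_b = [], []
        for b in range(nb):
            B = X[:, b, :]
            G = B @ B.T
            if np.any(np.diag(G) == 0):
                raise SignalError("all-zero band signal; cannot orthogonalize")
            gram.append(G)
            mean_b.append(B.mean(axis=-1))

        # Chunk by reference node so peak memory stays at a few
        # n_nodes x n_bands x samples blocks even for large parcellations.
        for i in range(n):
            R = np.empty((n, nb, T))
            for b in range(nb):
                G = gram[b]
                coef = G[i] / G[i, i]  # <x_i, x_j>/<x_i, x_i>
                R[:, b, :] = X[:, b, :] - coef[:, None] * X[i, b, :]
                # var(R_j) from the Gram entries and row means
                mr = mean_b[b] - coef * mean_b[b][i]
                e2 = (np.diag(G) - 2 * coef * G[i] + coef**2 * G[i, i]) / T
                var_r = np.maximum(e2 - mr**2, 0.0)
                var_y = np.maximum(np.diag(G) / T - mean_b[b] ** 2,
                                   np.finfo(float).tiny)
                res_ok[i, :, b] = var_r >= COLLINEARITY_TOL * var_y
            res_env_i = zscore(env_trimmed(R))  # (j, b, T')
            r1[i] = np.einsum("at,jbt->ajb", env_raw[i], res_env_i) / Tp
    else:
        for i in range(n):
            r1[i] = np.einsum("at,jbt->ajb", env_raw[i], env_raw) / Tp
    r = 0.5 * (r1 + r1.transpose(2, 3, 0, 1))

    defined = np.ones((n, nb, n, nb), dtype=bool)
    same_node = np.eye(n, dtype=bool)
    defined &= ~same_node[:, None, :, None]
    ok = np.broadcast_to(res_ok[:, None, :, :], defined.shape)  # (i,a,j,b)
    defined &= ok
    defined &= ok.transpose(2, 3, 0, 1)
    defined &= np.isfinite(r)

    r = np.where(defined, r, np.nan)
    values = r.reshape(n * nb, n * nb)
    return MultiLayerRSFC(
        values=values,
        defined=defined.reshape(n * nb, n * nb),
        conn=conn,
        power=power_estimate(subject, noise_variance),
    )


def mean_network(ml: MultiLayerRSFC, conn: ConnectomeDef) -> MeanNetworkRSFC:
    """Aggregate a multi-layer matrix into mean network couplings.

    Within-network entries average all defined intra-network node pairs;
    cross-network entries average all defined inter-network node pairs.
    Node-level power is averaged within each network.  A network with fewer
    than two nodes has an undefined (NaN) within-network entry.
    """
    nets = conn.networks
    nb = conn.n_bands
    members = {nw: conn.network_nodes(nw) for nw in nets}
    k = len(nets)
    vals = np.full((k * nb, k * nb), np.nan)
    counts = np.zeros((k * nb, k * nb), dtype=int)

    V = ml.values.reshape(conn.n_nodes, nb, conn.n_nodes, nb)
    D = ml.defined.reshape(conn.n_nodes, nb, conn.n_nodes, nb)

    for u, nu in enumerate(nets):
        for v, nv in enumerate(nets[u:], start=u):
            iu, iv = members[nu], members[nv]
            if u == v:
                pairs = [(i, j) for ii, i in enumerate(iu) for j in iu[ii + 1:]]
            else:
                pairs = [(i, j) for i in iu for j in iv]
            for a in range(nb):
                for b in range(nb):
                    if u == v and b < a:
                        continue
                    acc = [V[i, a, j, b] for i, j in pairs if D[i, a, j, b]]
                    # same-network cross-band: (i,a,j,b) and (j,a,i,b) are
                    # distinct multi-layer entries but the same unordered
                    # network entry; include both orientations.
                    if u == v and a != b:
                        acc += [V[j, a, i, b] for i, j in pairs if D[j, a, i, b]]
                    p = u * nb + a
                    q = v * nb + b
                    if acc:
                        m = float(np.mean(acc))
                        vals[p, q] = vals[q, p] = m
                        counts[p, q] = counts[q, p] = len(acc)

    net_power = None
    if ml.power is not None:
        net_power = np.vstack(
            [ml.power.values[members[nw], :].mean(axis=0) for nw in nets]
        )
    return MeanNetworkRSFC(values=vals, counts=counts, networks=nets,
                           conn=conn, network_power=net_power)


# ---------------------------------------------------------------------------
# Long-format export

def multilayer_to_frame(ml: MultiLayerRSFC):
    """Long-format table (node_i, band_a, node_j, band_b, r) of defined
    entries with i<j or (i==j excluded), one row per unordered entry."""
    import pandas as pd

    conn = ml.conn
    nb = conn.n_bands
    rows = []
    for p in range(conn.n_entries):
        for q in range(p + 1, conn.n_entries):
            if not ml.defined[p, q]:
                continue
            i, a = conn.unflatten(p)
            j, b = conn.unflatten(q)
            rows.append(
                dict(node_i=conn.nodes[i].label, band_a=conn.bands[a].name,
                     node_j=conn.nodes[j].label, band_b=conn.bands[b].name,
                     r=ml.values[p, q])
            )
    return pd.DataFrame(rows)
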