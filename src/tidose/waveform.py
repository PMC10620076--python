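"""Pulsed theta-burst TI waveform synthesis and envelope validation.

The protocol keeps channel 1 at a constant carrier f1 while channel 2
is frequency-shift keyed: during each shift window inside a train its
frequency moves from f1 to f1 + df, producing df-frequency amplitude
modulation (a burst of envelope pulses); outside shift windows both
channels run at f1 and the summed envelope is flat (unmodulated HF
exposure, not silence).  With the defaults -- f1 = 2 kHz, df = 100 Hz,
30 ms shift windows every 200 ms within 2 s trains repeated every 10 s
-- each burst carries 3 envelope pulses at 100 Hz, bursts repeat at the
5 Hz theta rhythm, and the mean carrier during a shift window is
2.05 kHz.  The HF control mode never shifts, so its envelope stays
flat.

Switching is phase-continuous: channel 2 accumulates phase from its
instantaneous frequency, so no sample-level discontinuity occurs.
Because df times the shift-window length is an integer number of beat
cycles, the two channels return to phase alignment at the end of every
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, hilbert

from .errors import ConfigurationError

TTIS = "tTIS"
HF_CONTROL = "HF-control"


@dataclass(frozen=True)
class WaveformProtocol:
    """Pulsed TI protocol parameters (defaults: the striatal protocol)."""

    fs_Hz: float = 100_000.0
    f1_Hz: float = 2000.0
    delta_f_Hz: float = 100.0
    shift_window_ms: float = 30.0
    burst_period_ms: float = 200.0
    train_duration_s: float = 2.0
    train_period_s: float = 10.0
    session_duration_s: float = 35.0
    ramp_s: float = 5.0
    amplitude_per_channel_mA: float = 2.0
    mode: str = TTIS

    def validate(self) -> None:
        if self.mode not in (TTIS, HF_CONTROL):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not self.shift_window_ms < self.burst_period_ms:
            raise ConfigurationError(
                "constraint violated: shift_window_ms < burst_period_ms")
        if not self.train_duration_s < self.train_period_s:
            raise ConfigurationError(
                "constraint violated: train_duration_s < train_period_s")
        cycles = self.delta_f_Hz * self.shift_window_ms / 1000.0
        if not (cycles > 0 and abs(cycles - round(cycles)) < 1e-9):
            raise ConfigurationError(
                "constraint violated: delta_f * shift_window must be a "
                f"positive whole number of beat cycles (got {cycles})")
        if self.fs_Hz < 20.0 * (self.f1_Hz + self.delta_f_Hz):
            raise ConfigurationError(
                "constraint violated: fs_Hz >= 20 * (f1 + delta_f)")
        if self.amplitude_per_channel_mA < 0:
            raise ConfigurationError("amplitude must be nonnegative")

    @property
    def pulses_per_burst_nominal(self) -> int:
        return int(round(self.delta_f_Hz * self.shift_window_ms / 1000.0))


@dataclass
class ChannelSignals:
    """Sampled two-channel currents plus shift-window annotations."""

    t: np.ndarray                 # seconds
    ch1: np.ndarray               # mA
    ch2: np.ndarray               # mA
    fs_Hz: float
    protocol: WaveformProtocol
    shift_windows: list = field(default_factory=list)  # (start_s, end_s)

    @property
    def summed(self) -> np.ndarray:
        return self.ch1 + self.ch2


@dataclass
class EnvelopeTrace:
    """Envelope of the summed channels (magnitude of the analytic signal)."""

    t: np.ndarray
    envelope: np.ndarray
    fs_Hz: float
    protocol: WaveformProtocol


def _ramp_profile(t: np.ndarray, total_s: float, ramp_s: float) -> np.ndarray:
    amp = np.ones_like(t)
    if ramp_s > 0:
        amp = np.minimum(amp, t / ramp_s)
        amp = np.minimum(amp, np.maximum(0.0, (total_s - t) / ramp_s))
        amp = np.clip(amp, 0.0, 1.0)
    return amp


def synthesize(protocol: WaveformProtocol) -> ChannelSignals:
    """Generate the two channel currents for one session.

    Channel 1 is a constant-frequency carrier; channel 2 follows the
    frequency-shift schedule (tTIS mode) or stays at f1 (HF control).
    Linear amplitude ramps of ``ramp_s`` are applied at both session
    ends.
    """
    protocol.validate()
    fs = protocol.fs_Hz
    n = int(round(protocol.session_duration_s * fs))
    t = np.arange(n) / fs

    # channel-2 instantaneous frequency
    f2 = np.full(n, protocol.f1_Hz)
    windows: list[tuple[float, float]] = []
    if protocol.mode == TTIS:
        # the ramp precedes the train schedule: the first train starts
        # once full amplitude is reached
        train_start = protocol.ramp_s
        while train_start < protocol.session_duration_s:
            w = train_start
            train_end = train_start + protocol.train_duration_s
            while w + protocol.shift_window_ms / 1000.0 <= train_end + 1e-12:
                w_end = w + protocol.shift_window_ms / 1000.0
                windows.append((w, min(w_end, protocol.session_duration_s)))
                w += protocol.burst_period_ms / 1000.0
            train_start += protocol.train_period_s
        for (w0, w1) in windows:
            i0, i1 = int(round(w0 * fs)), int(round(w1 * fs))
            f2[i0:i1] = protocol.f1_Hz + protocol.delta_f_Hz

    amp = protocol.amplitude_per_channel_mA * _ramp_profile(
        t, protocol.session_duration_s, protocol.ramp_s)
    ch1 = amp * np.sin(2 * np.pi * protocol.f1_Hz * t)
    # phase-continuous frequency keying: integrate instantaneous frequency
    phase2 = 2 * np.pi * np.cumsum(f2) / fs
    phase2 = np.concatenate([[0.0], phase2[:-1]])
    ch2 = amp * np.sin(phase2)
    return ChannelSignals(t=t, ch1=ch1, ch2=ch2, fs_Hz=fs,
                          protocol=protocol, shift_windows=windows)


def extract_envelope(signals: ChannelSignals) -> EnvelopeTrace:
    """Analytic-signal envelope of the summed channels.

    The first and last few carrier cycles are trimmed so the Hilbert
    transform's edge transients never enter downstream measurements.
    """
    env = np.abs(hilbert(signals.summed))
    guard = int(round(5 * signals.fs_Hz / signals.protocol.f1_Hz))
    if 2 * guard < env.size:
        sl = slice(guard, env.size - guard)
    else:
        sl = slice(None)
    return EnvelopeTrace(t=signals.t[sl], envelope=env[sl],
                         fs_Hz=signals.fs_Hz, protocol=signals.protocol)


def _modulation_depth(trace: EnvelopeTrace) -> np.ndarray:
    """AM depth signal: how far the envelope dips below its plateau.

    Outside bursts the summed channels are in phase and the envelope
    sits at its plateau (twice the per-channel amplitude); inside a
    burst it swings down toward zero once per beat cycle.  Envelope
    pulses are therefore counted as excursions of this depth signal.
    """
    return float(trace.envelope.max()) - trace.envelope


# an AM excursion must reach at least this fraction of the envelope
# plateau to count as modulation at all (rejects HF-control ripple)
_MIN_DEPTH_FRACTION = 0.05


def _pulse_peaks(trace: EnvelopeTrace) -> np.ndarray:
    """Sample indices of envelope pulses (beat-cycle AM excursions)."""
    depth = _modulation_depth(trace)
    top = float(depth.max())
    if top < _MIN_DEPTH_FRACTION * float(trace.envelope.max()):
        return np.array([], dtype=int)
    beat = 1.0 / trace.protocol.delta_f_Hz
    min_dist = max(1, int(round(0.5 * beat * trace.fs_Hz)))
    peaks, _ = find_peaks(depth, height=0.5 * top, distance=min_dist)
    return peaks


def count_envelope_pulses(trace: EnvelopeTrace,
                          window: tuple[float, float]) -> int:
    """Number of envelope pulses inside the time window (seconds).

    A pulse is one beat-cycle amplitude-modulation excursion: a local
    maximum of the AM depth signal reaching at least half the global
    depth, with minimum separation of half a beat period.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ConfigurationError("empty pulse-count window")
    peaks = _pulse_peaks(trace)
    times = trace.t[peaks] if peaks.size else np.array([])
    return int(np.count_nonzero((times >= t0) & (times <= t1)))


def burst_train_statistics(trace: EnvelopeTrace
                           ) -> tuple[float, float, int, float]:
    """Measure (burst_rate_Hz, train_period_s, pulses_per_burst, am_frequency_Hz).

    Bursts are clusters of envelope pulses separated by less than half a
    burst period; trains are clusters of bursts separated by more than
    two burst periods.  The AM frequency is the spectral peak of the
    envelope inside bursts.  HF-control traces (no modulation) return
    zeros.
    """
    p = trace.protocol
    peaks = _pulse_peaks(trace)
    if peaks.size == 0:
        if p.mode == HF_CONTROL:
            return 0.0, 0.0, 0, 0.0
        raise ConfigurationError("no bursts detected in a tTIS-mode trace")

    times = trace.t[peaks]
    burst_gap = 0.5 * p.burst_period_ms / 1000.0
    bursts: list[list[int]] = [[0]]
    for i in range(1, times.size):
        if times[i] - times[bursts[-1][-1]] > burst_gap:
            bursts.append([i])
        else:
            bursts[-1].append(i)
    burst_onsets = np.array([times[b[0]] for b in bursts])
    pulse_counts = np.array([len(b) for b in bursts])

    # burst rate: onset-to-onset differences *within* trains
    gaps = np.diff(burst_onsets)
    train_gap = 2.0 * p.burst_period_ms / 1000.0
    within = gaps[gaps < train_gap]
    burst_rate = float(1.0 / within.mean()) if within.size else 0.0

    # train onsets: first burst after a long quiescent gap
    train_starts = [burst_onsets[0]]
    for g, onset in zip(gaps, burst_onsets[1:]):
        if g >= train_gap:
            train_starts.append(onset)
    train_period = (float(np.diff(train_starts).mean())
                    if len(train_starts) >= 2 else 0.0)

    counts, values = np.histogram(pulse_counts,
                                  bins=np.arange(0.5, pulse_counts.max() + 1.5))
    pulses_per_burst = int(np.argmax(counts) + 1)

    am_frequency = _burst_spectral_peak(trace, bursts, peaks)
    return burst_rate, train_period, pulses_per_burst, am_frequency


def _burst_spectral_peak(trace: EnvelopeTrace, bursts: list, peaks: np.ndarray
                         ) -> float:
    """Dominant envelope frequency inside bursts.

    The envelope restricted to the burst intervals is concatenated
    (bursts are beat-phase coherent because each shift window spans
    whole beat cycles), which gives the AM line a long integration time
    and removes the leakage bias a single 30-ms burst would suffer; the
    peak of the zero-padded spectrum of the concatenation is returned.
    """
    p = trace.protocol
    fs = trace.fs_Hz
    beat = 1.0 / p.delta_f_Hz
    half = int(round(0.5 * beat * fs))
    seg_len = int(round(beat * fs))
    segs = []
    for b in bursts:
        i0 = peaks[b[0]] - half
        i1 = i0 + len(b) * seg_len
        if i0 >= 0 and i1 <= trace.envelope.size:
            segs.append(trace.envelope[i0:i1])
    if not segs:
        return 0.0
    cat = np.concatenate(segs)
    cat = cat - cat.mean()
    nfft = max(1 << 21, cat.size)
    spec = np.abs(np.fft.rfft(cat, n=nfft))
    k = 1 + int(np.argmax(spec[1:]))  # skip the DC bin
    return float(k * fs / nfft)


@dataclass
class SessionSchedule:
    """Ordered stimulation-on intervals of one experimental session."""

    template: str
    intervals: list            # (block_index, start_s, end_s, tag)

    @property
    def total_stim_on_s(self) -> float:
        return float(sum(e - s for _, s, e, tag in self.intervals
                         if tag == "task"))


def session_schedule(template: str) -> tuple[SessionSchedule, float]:
    """Stimulation schedule for the two experiment templates.

    * ``experiment1``: six blocks of ten 30-s task repetitions
      alternated with 30-s rest; stimulation only during task
      repetitions (total 30 min of stimulation).
    * ``experiment2``: seven 90-s task blocks alternated with 90-s
      breaks; stimulation during the task blocks (total 10 min 30 s).
    """
    intervals = []
    if template == "experiment1":
        t = 0.0
        for block in range(6):
            for rep in range(10):
                intervals.append((block, t, t + 30.0, "task"))
                t += 30.0
                if rep < 9:
                    intervals.append((block, t, t + 30.0, "rest"))
                    t += 30.0
            t += 90.0  # inter-block break
    elif template == "experiment2":
        t = 0.0
        for block in range(7):
            intervals.append((block, t, t + 90.0, "task"))
            t += 90.0
            if block < 6:
                intervals.append((block, t, t + 90.0, "rest"))
                t += 90.0
    elif template == "empty":
        pass
    else:
        raise ConfigurationError(f"unknown session template {template!r}")
    sched = SessionSchedule(template=template, intervals=intervals)
    return sched, sched.total_stim_on_s


def zero_crossing_frequency(x: np.ndarray, fs_Hz: float) -> float:
    """Frequency estimate from linearly interpolated zero-crossing times.

    With k crossings at times t_1 < ... < t_k the estimate is
    (k - 1) / (2 (t_k - t_1)); interpolation makes it accurate to well
    below 0.1% for clean sinusoids over a few cycles.
    """
    x = np.asarray(x, dtype=float)
    signs = np.signbit(x)
    idx = np.flatnonzero(signs[1:] != signs[:-1])
    if idx.size < 2:
        return 0.0
    frac = x[idx] / (x[idx] - x[idx + 1])
    times = (idx + frac) / fs_Hz
    return float((idx.size - 1) / (2.0 * (times[-1] - times[0])))
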