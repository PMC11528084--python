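"""End-to-end orchestration: stimuli -> simulated EEG -> responses -> tables.

A run sweeps a condition grid (paradigm x stimulus frequency x rate x
high-pass-noise cutoff) over one or more "subjects" (independent seeds of
the forward model), extracts the responses, picks wave-V latencies, forms
derived bands, and writes tidy CSV tables — the exact shape an external
mixed-effects fit would consume.  Everything is deterministic given the
master seed: per-condition and per-subject seeds are derived from it via
``numpy.random.SeedSequence`` spawn keys and logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import derived_band as db
from . import io as pio
from . import response_extraction as rex
from . import stimulus as stim
from . import synthetic_eeg as seeg

__all__ = [
    "RunConfig",
    "load_config",
    "run_pipeline",
    "total_recording_minutes",
    "n_masker_conditions",
    "minutes_per_condition",
    "simulate_and_extract",
    "grand_average",
]

logger = logging.getLogger(__name__)


# -- session arithmetic -------------------------------------------------------

def total_recording_minutes(n_sessions: int = 4, minutes_per_session: float = 150.0) -> float:
    """Total recording time per subject across sessions."""
    return n_sessions * minutes_per_session


def n_masker_conditions(n_parallel_cutoffs: int = 13, serial_cutoff_counts: tuple[int, ...] = (7, 7)) -> int:
    """Number of distinct masker conditions in a session plan.

    Serial runs for different test frequencies share presentation slots
    (one test frequency per ear), so the serial conditions count once:
    13 parallel + 7 serial = 20 with the standard grids.
    """
    return n_parallel_cutoffs + (max(serial_cutoff_counts) if serial_cutoff_counts else 0)


def minutes_per_condition(
    total_minutes: float = 600.0, n_masker: int = 20, n_rates: int = 3
) -> float:
    return total_minutes / (n_masker * n_rates)


# -- configuration ------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative description of one simulated recording study."""

    paradigms: tuple[str, ...] = ("parallel", "serial")
    frequencies_hz: tuple[float, ...] = stim.STANDARD_FREQUENCIES_HZ
    serial_frequencies_hz: tuple[float, ...] = (500.0, 2000.0)
    rates_per_s: tuple[float, ...] = stim.STANDARD_RATES_PER_S
    parallel_cutoffs_hz: tuple[float, ...] | None = None  # None -> full 13-step grid
    analysis_frequencies_hz: tuple[float, ...] | None = None  # None -> all stimulus frequencies
    n_subjects: int = 1
    minutes_per_condition_min: float = 10.0
    seed: int = 0
    stimulus_fs_hz: float = 48_000.0
    band_model: seeg.CochlearBandModel = field(default_factory=seeg.CochlearBandModel)
    noise_model: seeg.NoiseModel = field(default_factory=seeg.NoiseModel)
    write_artifacts: bool = False

    def __post_init__(self) -> None:
        if self.minutes_per_condition_min <= 0:
            raise ValueError("minutes_per_condition_min must be positive")
        grid = set(stim.half_octave_steps(250.0, 17))
        for f in tuple(self.frequencies_hz) + tuple(self.serial_frequencies_hz):
            if int(round(f)) not in grid:
                raise ValueError(f"frequency {f} Hz is not on the half-octave grid")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a TOML file (flat keys matching field names)."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    band = seeg.CochlearBandModel(**{k: v for k, v in raw.pop("band_model", {}).items()})
    noise = seeg.NoiseModel(**{k: v for k, v in raw.pop("noise_model", {}).items()})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
    return RunConfig(band_model=band, noise_model=noise, **cfg)


# -- building blocks ----------------------------------------------------------

def _condition_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master, spawn_key=tuple(key))


def draw_condition_trains(
    frequencies_hz: tuple[float, ...],
    rate_per_s: float,
    duration_s: float,
    seed_seq: np.random.SeedSequence,
    fs_hz: float = 48_000.0,
) -> dict[float, stim.ImpulseTrain]:
    """Independent Poisson trains for every stimulus frequency."""
    children = seed_seq.spawn(len(frequencies_hz))
    return {
        f: stim.draw_impulse_train(rate_per_s, duration_s, np.random.default_rng(c), fs_hz)
        for f, c in zip(frequencies_hz, children)
    }


def search_window_ms(frequency_hz: float, cutoff_hz: float | None) -> tuple[float, float]:
    """Wave-V search window, widened where later responses are expected."""
    if frequency_hz <= 500 or (cutoff_hz is not None and cutoff_hz <= 500):
        return (4.0, 24.0)
    return (4.0, 20.0)


def simulate_and_extract(
    paradigm: str,
    test_frequency_hz: float | None,
    rate_per_s: float,
    cutoff_hz: float | None,
    config: RunConfig,
    subject: int,
    condition_index: int,
    analysis_frequencies_hz: tuple[float, ...] | None = None,
) -> dict[float, rex.ResponseWaveform]:
    """Simulate one condition for one subject and extract its responses.

    Returns responses keyed by analysis frequency (serial: the test
    frequency only).  All randomness derives from the master seed, the
    subject index and the condition index.
    """
    duration_s = config.minutes_per_condition_min * 60.0
    ss = _condition_seed(config.seed, subject, condition_index)
    train_ss, sim_ss = ss.spawn(2)
    trains = draw_condition_trains(
        config.frequencies_hz, rate_per_s, duration_s, train_ss, config.stimulus_fs_hz
    )
    rec = seeg.simulate_condition(
        paradigm,
        rate_per_s,
        cutoff_hz,
        trains,
        config.band_model,
        config.noise_model,
        seed=sim_ss,
        test_frequency_hz=test_frequency_hz,
    )
    if paradigm == "serial":
        freqs = (test_frequency_hz,)
    else:
        freqs = analysis_frequencies_hz or config.frequencies_hz
    out: dict[float, rex.ResponseWaveform] = {}
    for f in freqs:
        idx = rex.downsample_impulses(trains[f], rec.fs_hz, warn_on_collision=False)
        out[f] = rex.extract_condition(
            rec.samples,
            rec.fs_hz,
            idx,
            rec.trial_boundaries,
            condition={
                "paradigm": paradigm,
                "frequency_hz": f,
                "rate_per_s": rate_per_s,
                "hpn_cutoff_hz": cutoff_hz,
                "subject": subject,
            },
        )
    return out


def grand_average(responses: list[rex.ResponseWaveform]) -> rex.ResponseWaveform:
    """Unweighted mean of per-subject averaged responses."""
    if not responses:
        raise ValueError("nothing to average")
    w = np.mean([r.w for r in responses], axis=0)
    return rex.ResponseWaveform(
        w=w,
        fs_hz=responses[0].fs_hz,
        lag_start_s=responses[0].lag_start_s,
        n_stimuli=int(np.sum([r.n_stimuli for r in responses])),
        condition={k: v for k, v in responses[0].condition.items() if k != "subject"},
    )


# -- the full run -------------------------------------------------------------

def _conditions(config: RunConfig):
    """Yield (paradigm, test_frequency, rate, cutoff) in deterministic order."""
    i = 0
    for paradigm in config.paradigms:
        if paradigm == "parallel":
            grid = stim.enumerate_conditions("parallel", rates=config.rates_per_s)
            cutoffs = config.parallel_cutoffs_hz or grid.hpn_cutoffs_hz
            for rate in config.rates_per_s:
                for c in cutoffs:
                    yield i, paradigm, None, rate, c
                    i += 1
        else:
            for f in config.serial_frequencies_hz:
                grid = stim.enumerate_conditions("serial", f, rates=config.rates_per_s)
                for rate in config.rates_per_s:
                    for c in grid.hpn_cutoffs_hz:
                        yield i, paradigm, f, rate, c
                        i += 1


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the whole study and write latency and derived-band size tables.

    Writes ``latencies.csv`` (one row per subject x paradigm x frequency x
    rate x cutoff), ``derived_sizes.csv`` (one row per subject x paradigm
    x frequency x rate x derived band), and ``run_log.json``.  With
    ``write_artifacts`` also exports a stimulus token (WAV + JSON trains)
    and one EDF recording per condition.  Partial outputs are removed if
    the run fails.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        return _run(config, out_dir, created)
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, out_dir: Path, created: list[Path]) -> Path:
    # responses[(paradigm, freq, rate)][cutoff] -> list over subjects
    store: dict[tuple, dict[float, list[rex.ResponseWaveform]]] = {}
    for i, paradigm, test_f, rate, cutoff in _conditions(config):
        for subject in range(config.n_subjects):
            res = simulate_and_extract(
                paradigm, test_f, rate, cutoff, config, subject, i,
                analysis_frequencies_hz=config.analysis_frequencies_hz,
            )
            for f, r in res.items():
                store.setdefault((paradigm, f, rate), {}).setdefault(cutoff, []).append(r)
        logger.info("condition %d done: %s f=%s rate=%s cutoff=%s", i, paradigm, test_f, rate, cutoff)

    lat_rows, size_rows = [], []
    for (paradigm, f, rate), by_cutoff in store.items():
        grand = {c: grand_average(rs) for c, rs in by_cutoff.items()}
        grand_lat = {
            c: db.pick_wave_v(g, search_window_ms(f, c)) for c, g in grand.items()
        }
        subj_lat: dict[tuple[int, float], float | None] = {}
        for c, rs in by_cutoff.items():
            for s, r in enumerate(rs):
                lat = db.pick_wave_v(r, search_window_ms(f, c))
                subj_lat[(s, c)] = lat
                lat_rows.append(
                    dict(
                        subject=s,
                        paradigm=paradigm,
                        frequency_hz=f,
                        rate_per_s=rate,
                        hpn_cutoff_hz=c,
                        latency_ms=np.nan if lat is None else lat,
                        n_stimuli=r.n_stimuli,
                    )
                )
        # The analysis window for each derived band is centred on the mean
        # of the parent grand-average latencies (individual subjects do not
        # always show a response); a band whose parents lack a grand-average
        # peak is excluded.
        for s in range(config.n_subjects):
            subj_resp = {c: rs[s] for c, rs in by_cutoff.items()}
            for d in db.derive_bands(subj_resp):
                lo, hi = d.parent_cutoffs_hz
                center = db.expected_window(grand_lat.get(lo), grand_lat.get(hi))
                excluded = center is None
                size_rows.append(
                    dict(
                        subject=s, paradigm=paradigm, frequency_hz=f, rate_per_s=rate,
                        band_center_hz=d.center_hz,
                        sigma_r_v=np.nan if excluded else db.estimate_size(d, center).sigma_r_v,
                        window_center_ms=np.nan if excluded else center,
                        excluded=excluded,
                    )
                )

    lat_path = out_dir / "latencies.csv"
    size_path = out_dir / "derived_sizes.csv"
    created += [lat_path, size_path]
    pd.DataFrame(lat_rows).to_csv(lat_path, index=False, float_format="%.10g")
    pd.DataFrame(size_rows).to_csv(size_path, index=False, float_format="%.10g")

    if config.write_artifacts:
        created += _write_example_artifacts(config, out_dir)

    log_path = out_dir / "run_log.json"
    created.append(log_path)
    log = {
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "minutes_per_condition": config.minutes_per_condition_min,
        "numpy_version": np.__version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    log_path.write_text(json.dumps(log, indent=2, default=str))
    return out_dir


def _write_example_artifacts(config: RunConfig, out_dir: Path) -> list[Path]:
    """One example stimulus token (WAV + train JSONs) and one EDF recording."""
    created = []
    rate = config.rates_per_s[0]
    ss = _condition_seed(config.seed, 9999)
    trains = draw_condition_trains(config.frequencies_hz, rate, 1.0, ss, config.stimulus_fs_hz)
    bursts = {
        f: stim.make_toneburst(stim.ToneburstSpec(f, sample_rate_hz=config.stimulus_fs_hz))
        for f in config.frequencies_hz
    }
    token = stim.assemble_stimulus(trains, bursts, "parallel")
    masker = stim.make_hpn_masker(
        stim.MaskerSpec(cutoff_hz=1000.0, sample_rate_hz=config.stimulus_fs_hz), 1.0,
        np.random.default_rng(ss.spawn(1)[0]),
    )
    created.append(pio.write_wav(out_dir / "example_token.wav", token + masker, config.stimulus_fs_hz))
    for f, t in trains.items():
        created.append(pio.train_to_json(t, out_dir / f"example_train_{int(f)}Hz.json", f))
    rec = seeg.simulate_condition(
        "parallel", rate, 1000.0, trains, config.band_model, config.noise_model, seed=ss.spawn(1)[0]
    )
    created.append(pio.write_edf(out_dir / "example_recording.edf", rec.samples, rec.fs_hz))
    return created
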