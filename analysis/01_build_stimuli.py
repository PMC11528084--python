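"""Build and verify the stimulus conditions.

Enumerates the paradigm/cutoff grids and session arithmetic, synthesizes
example tokens, and verifies the masker design by power spectral density:
high-pass attenuation one octave below the cutoff and the pink (-3
dB/octave) passband slope.  Writes ``results/stimulus_conditions.csv`` and
``results/masker_verification.csv``.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from pabr.pipeline import minutes_per_condition, n_masker_conditions, total_recording_minutes
from pabr.stimulus import (
    MaskerSpec,
    ToneburstSpec,
    assemble_stimulus,
    draw_impulse_train,
    enumerate_conditions,
    make_hpn_masker,
    make_toneburst,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)
FS = 48_000.0


def condition_table() -> pd.DataFrame:
    rows = []
    grids = [enumerate_conditions("parallel")] + [
        enumerate_conditions("serial", f) for f in (500.0, 2000.0)
    ]
    for g in grids:
        for rate in g.rates:
            for c in g.hpn_cutoffs_hz:
                rows.append(
                    dict(
                        paradigm=g.paradigm,
                        test_frequency_hz=g.test_frequency_hz,
                        rate_per_s=rate,
                        hpn_cutoff_hz=c,
                        tokens=g.tokens,
                        token_duration_s=g.token_duration_s,
                    )
                )
    return pd.DataFrame(rows)


def masker_table() -> pd.DataFrame:
    rows = []
    for cutoff in (250.0, 1000.0, 4000.0, None):
        x = make_hpn_masker(MaskerSpec(cutoff_hz=cutoff, sample_rate_hz=FS), 4.0, seed=1)
        f, psd = sps.welch(x, fs=FS, nperseg=16384)
        sel = (f >= 100) & (f <= 10_000)
        slope = np.polyfit(np.log2(f[sel]), 10 * np.log10(psd[sel]), 1)[0]
        if cutoff:
            below = np.mean(psd[(f > cutoff / 2 * 0.8) & (f < cutoff / 2 * 1.2)])
            above = np.mean(psd[(f > cutoff * 1.8) & (f < cutoff * 2.2)])
            atten = 10 * np.log10(above / below)
        else:
            atten = np.nan
        rows.append(
            dict(
                cutoff_hz=cutoff,
                attenuation_octave_below_db=atten,
                passband_slope_db_per_octave=slope if cutoff is None else np.nan,
            )
        )
    return pd.DataFrame(rows)


def main() -> None:
    grid = condition_table()
    grid.to_csv(RESULTS / "stimulus_conditions.csv", index=False)
    n_parallel = (grid["paradigm"] == "parallel").sum() // 3
    n_serial_500 = ((grid["paradigm"] == "serial") & (grid["test_frequency_hz"] == 500)).sum() // 3
    total = total_recording_minutes(4, 150.0)
    per_cond = minutes_per_condition(total, n_masker_conditions(13, (7, 7)), 3)
    print(f"{n_parallel} parallel masker conditions, {n_serial_500} serial (500 Hz)")
    print(f"session plan: {total:.0f} min total -> {per_cond:.0f} min per condition")

    masker = masker_table()
    masker.to_csv(RESULTS / "masker_verification.csv", index=False)
    worst = masker["attenuation_octave_below_db"].min()
    slope = masker["passband_slope_db_per_octave"].dropna().iloc[0]
    print(f"masker attenuation one octave below cutoff: worst {worst:.0f} dB (spec >= 60)")
    print(f"full-band pink slope: {slope:.2f} dB/octave (expected -3)")

    # an audible sanity check: one parallel token at 40/s with a 1 kHz masker
    freqs = (500.0, 1000.0, 2000.0, 4000.0, 8000.0)
    trains = {f: draw_impulse_train(40.0, 1.0, seed=i, sample_rate_hz=FS) for i, f in enumerate(freqs)}
    bursts = {f: make_toneburst(ToneburstSpec(f, sample_rate_hz=FS)) for f in freqs}
    token = assemble_stimulus(trains, bursts, "parallel")
    print(f"example parallel token RMS: {np.sqrt(np.mean(token**2)):.4f} full scale")


if __name__ == "__main__":
    main()
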