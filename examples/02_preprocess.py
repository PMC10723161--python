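"""Temporal preprocessing of one simulated BOLD run.

Shows the fixed stage order — drop the first 10 volumes, jointly regress
out the linear trend, Friston-24 motion expansion and WM/CSF mean signals,
then band-pass 0.01-0.1 Hz — and what each stage does to the variance and
spectrum of a gray-matter voxel.
"""
import numpy as np

import seedfc as s

scene = s.default_scene(("DMN",), rng_seed=7)
table = s.generate_participants((2, 2, 2), rng_seed=7)
img, motion, masks = s.simulate_bold(table.iloc[0], scene)

gm_voxel = tuple(np.argwhere(masks["gm"])[0])


def band_power(series, tr, lo, hi):
    freqs = np.fft.rfftfreq(len(series), tr)
    p = np.abs(np.fft.rfft(series)) ** 2
    sel = (freqs >= lo) & (freqs <= hi)
    return p[sel].sum() / p[1:].sum()  # exclude DC


raw = img.data[gm_voxel]
print(f"raw series: {img.n_volumes} volumes, sd {raw.std():.3f}, "
      f"in-band power fraction {band_power(raw, 2.0, 0.01, 0.1):.3f}")

dropped = s.drop_initial_volumes(img, 10)
fr24 = s.build_friston24(motion[10:])
print(f"after drop: {dropped.n_volumes} volumes; Friston-24 block "
      f"{fr24.regressors.shape} ({fr24.labels[0]} ... {fr24.labels[-1]})")

clean, motion_out = s.preprocess_bold(img, motion, masks["wm"], masks["csf"])
series = clean.data[gm_voxel]
print(f"after full preprocessing: sd {series.std():.3f}, "
      f"in-band power fraction {band_power(series, 2.0, 0.01, 0.1):.3f}")
# The in-band fraction approaches 1: drift, motion-locked artifact and the
# shared WM/CSF signals are gone and only 0.01-0.1 Hz fluctuations remain,
# which is the regime seed-based resting-state correlation analysis assumes.
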