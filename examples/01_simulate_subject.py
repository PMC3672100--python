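"""Generate one synthetic subject (paired cvBOLD + ASL) and inspect it.

The generator plants band-limited (0.01-0.08 Hz) network time courses in
known spatial maps, a labeling modulation on the ASL series that encodes a
known CBF map, per-voxel drift, and thermal noise.  Everything planted is
returned as ground truth for recovery experiments.
"""

import tempfile

import numpy as np

from aslrest import generate_subject, write_subject

subject = generate_subject(seed=1)

print(f"cvBOLD: {subject.cvbold.data.shape} volumes at TR {subject.cvbold.tr_s} s")
print(f"ASL:    {subject.asl.series.data.shape} volumes at TR {subject.asl.series.tr_s} s")
print(f"brain voxels: {subject.brain_mask.sum()} "
      f"(GM {subject.gm_mask.sum()}, WM {subject.wm_mask.sum()}, CSF {subject.csf_mask.sum()})")
print(f"planted networks: {[int(m.sum()) for m in subject.truth.network_maps]} voxels each")
print(f"true GM CBF: {subject.truth.cbf_true[subject.gm_mask].mean():.1f} ml/100g/min")
print(f"paradigm (first 6 volumes): {subject.asl.paradigm[:6]}  "
      f"({subject.metadata['paradigm_convention']})")

tc = subject.truth.network_timecourses_cv[0]
spec = np.abs(np.fft.rfft(tc)) ** 2
freqs = np.fft.rfftfreq(tc.size, subject.cvbold.tr_s)
inband = (freqs >= 0.01) & (freqs <= 0.08)
print(f"network time-course power inside 0.01-0.08 Hz: {spec[inband].sum() / spec.sum():.4f}")

with tempfile.TemporaryDirectory() as tmp:
    paths = write_subject(subject, tmp)
    print(f"wrote {len(paths)} files (NIfTI series/masks, paradigm.txt, truth.json)")
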