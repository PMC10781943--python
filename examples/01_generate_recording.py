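"""Generate one synthetic treadmill recording and write it as CSV files.

Builds a 4-stage incremental run (3-min stages, +0.28 m/s per stage) with
post-VT2 shifts planted on three features, then prints what the recording
contains. The ground-truth sidecar stores the planted VT2 time and the
per-step true feature values, which is what makes every later pipeline
stage testable.
"""
from runfatigue import EffectSpec, ProtocolSpec, generate_subject, write_recording

protocol = ProtocolSpec(n_stages=4, start_velocity=3.0)
effects = EffectSpec(shifts={"RT_APu": 1.0, "RFD_maxD": 0.75, "RT_LTu": 0.5})
rec = generate_subject(protocol, effects, seed=42)

write_recording(rec, "example_recording")

print(f"duration           : {protocol.duration:.0f} s ({protocol.n_stages} stages)")
print(f"GRF samples        : {rec.grf.size} at {protocol.grf_rate:.0f} Hz")
print(f"gyro samples       : {len(rec.gyro)} at {protocol.imu_rate:.0f} Hz x 6 axes")
print(f"breaths            : {len(rec.breaths)}")
print(f"steps generated    : {len(rec.true_steps)}")
print(f"planted VT2        : {rec.ground_truth['vt2_time']:.0f} s "
      f"({effects.vt2_fraction:.0%} of test)")
print(f"peak force         : {rec.grf.max():.0f} N "
      f"(~{rec.grf.max() / (rec.body_mass * 9.81):.2f} body weights)")
# The three CSVs plus ground_truth.json are now under example_recording/.
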