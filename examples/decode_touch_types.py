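"""Time-resolved decoding of the four touch types within one sensory field.

A diagonal-covariance LDA (shared pooled variance, independent units) is
trained on sliding 300 ms windows of spike counts and scored by
stratified leave-one-out cross-validation, per session, then averaged.
Chance is 0.25.  A coarser 100 ms step keeps this demo quick; the
standard step is 10 ms.
"""

from popcongruence import decoding, synth

spec = synth.PopulationGenSpec(n_units=40, n_sessions=2, seed=31,
                               model_mixture={"s1111": 1.0})
exp = synth.generate_population(spec, "MSMT")

curve = decoding.time_resolved_accuracy(exp.sessions, field="Ac",
                                        step=0.1, stop=3.0)
df = curve.summary()
for start in (-0.4, 0.0, 0.5, 1.5, 3.0):
    row = df.iloc[(df.window_start - start).abs().argmin()]
    print(f"window {row.window_start:+.2f}s: accuracy {row.accuracy:.2f} "
          f"(CI {row.ci_lo:.2f}-{row.ci_hi:.2f})")
# Pre-stimulus windows sit at chance; accuracy rises after the ~60 ms
# sensory latency and saturates while distinct selectivity patterns are
# active during stimulation.
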