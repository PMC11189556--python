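"""Administer the anticipated-response stop task and score it.

A responder with a known true stopping latency (200 ms) plays the full
schedule (10 + 20 practice, then 3 x 60 test trials at 25% stop).  The
integration method should estimate a value near 200 ms: the staircase
holds the stop-respond rate near 50%, and SSRT = go-RT quantile at that
rate minus the mean stop-signal delay.
"""

from eftrial import score_osari
from eftrial.policies import ResponderPolicy
from eftrial.tasks import run_osari

policy = ResponderPolicy("response_inhibition",
                         {"go_mean": 800.0, "go_sd": 50.0,
                          "ssrt_true": 200.0, "omission_rate": 0.02})
log = run_osari(policy, seed=7)
scores = score_osari(log)

print(f"test trials: {sum(t.block.startswith('test') for t in log.trials)} "
      f"(go 135 / stop 45 by design)")
print(f"estimated SSRT       : {scores.ssrt:6.1f} ms  (true 200 ms)")
print(f"go RT mean (sd)      : {scores.go_rt_mean:6.1f} ({scores.go_rt_sd:.1f}) ms")
print(f"stop-respond rate    : {scores.p_respond_stop:.2f}  (staircase targets 0.50)")
print(f"mean / max SSD       : {scores.mean_ssd:.0f} / {scores.max_ssd:.0f} ms")
print(f"QC pass              : {scores.qc_pass}")
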