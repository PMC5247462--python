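# bodyn — border-ownership dynamics in a V1 / V2 / parietal rate network

Border ownership (BO) is the assignment of a contour to the object
surface on one of its sides; most V2 neurons in primates are selective
for it.  Physiologically, BO signals collapse quickly when a figure is
flipped to the opposite side of a cell's receptive field, but only
slowly when the figure is replaced by an ambiguous edge that supports
either assignment.  `bodyn` is a simulator for studying that
time-course: a three-module rate network (V1 oriented contrast with
divisive normalization, V2 BO-selective cells driven by surround
facilitation/suppression, and a parietal saliency map feeding a weak
attentional contrast gain back to V1), integrated with fixed-step RK4
under per-unit current noise.

Every unit follows

    tau dA/dt = -A + mu F(A) - gamma F(A_inh) + I + eta,
    F(x) = 1 / (T_r - tau ln(1 - 1/(tau x)))   for tau x > 1, else 0,

with tau = 10 ms, T_r = 0.5 ms, mu = 0.95, gamma = 0.8, uniform noise
eta in ±0.25.  The BO signal is the summed discharge rate of the
left-preferring minus right-preferring populations at the recorded edge,
nu(t) in Hz.  Five experiments are built in: square→ambiguous-edge
replacement vs. square flip, a figure-duration sweep, repeated
presentations (signal reset), spatial cueing of detection times, and
attention-pulled bi-stable random-block figures.  The scientific
rationale, calibration and numerical choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from bodyn import RunConfig, BONetwork
from bodyn.stimuli import build_protocol_sequence
from bodyn.analysis import decay_time, response_time

cfg = RunConfig(grid=50)          # the calibrated half-scale configuration
net = BONetwork(cfg)

# a left-owned square for 500 ms, then the ambiguous edge
seq, cue = build_protocol_sequence("ambiguous", grid=cfg.grid, t_end=850.0)
trace, _ = net.run_trial(seq, cue, seed=1)
print(f"response time: {response_time(trace):.1f} ms")
print(f"decay time:    {decay_time(trace, switch_time=500.0):.1f} ms")
```

prints (seed 1):

```
response time: 41.3 ms
decay time:    621.6 ms
```

The response time is when the BO signal first exceeds 10 Hz after the
square appears — the model's detection latency.  The decay time is when
the signal first returns to 0 Hz after the 500 ms switch to the
ambiguous edge: ~130 ms of persistence, an order of magnitude longer
than the 10 ms membrane constant, produced by the near-critical
recurrence and the module-wide inhibition.  Flipping the square instead
(`build_protocol_sequence("flip", ...)`) drives the crossing ~70 ms
earlier (548.2 ms for the same seed).

A thin CLI wraps the same machinery:

```
bo-dynamics run ambiguous --grid 50 --trials 20 --out results.h5
bo-dynamics sweep --grid 50 --out sweep.csv
bo-dynamics kernels --out kernels.json
bo-dynamics report results.h5
```

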