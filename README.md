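# legsearch

Neuromechanical simulation of stick-insect front-leg **search movements**:
the cyclic, stereotyped up–down and flexion–extension movements a front leg
performs when it finds no ground contact, and how they recover after the
leg briefly hits an obstacle.

The package is for motor-control and computational-neuroscience researchers
who want an executable, fully deterministic version of the reduced one-leg
model: two local neuromuscular control networks — levator–depressor (femur
elevation β at the coxa–trochanter joint) and extensor–flexor (femur–tibia
angle γ; the tarsus angle α follows kinematically from β, γ and the segment
lengths) — each built from a half-center central pattern generator,
inhibitory premotor interneurons and fast/slow motoneuron pools, coupled by
threshold-gated two-valued sensory conductances g_β and g_γ.  The γ
threshold selects between two driving regimes (tonic excitation of the
levator–depressor network at γ_thr = 83°, periodic switching at 145°),
which in turn sets the qualitative shape of the β–γ state diagram
(triangle-like search loops vs quadrilateral stepping-like loops).

The obstacle experiment is built in: a brief (< 100 ms) contact silences
all motoneurons while passive muscle rigidity holds the posture; after
removal the slow motoneurons recover within 200 ms, the single fast
extensor/flexor motoneurons immediately, and the fast levator/depressor
pools are *gradually recruited* over `base_duration × rf(PO)`, where the
slow-down factor rf is linearly interpolated in the obstacle position PO:

    rf = (rf1 − rf0) / (PO1 − PO0) · (PO − PO0) + rf0,   rf ≥ 1.

An analysis layer classifies β–γ loops, detects oscillation cessation and
alternating-amplitude oscillations, and drives obstacle-position sweeps.

See `docs/methods.md` for the model equations, calibrated defaults and
known limitations.

## Worked example

```python
import legsearch as ls
from legsearch.protocol import run_obstacle_experiment
import legsearch.analysis as an

cfg = ls.default_config("tonic_b4")        # gamma_thr=83, beta_thr=4
trace = run_obstacle_experiment(cfg, po_deg=15.0)

print({k: round(v, 1) for k, v in trace.events.items()})
pre = trace.segment(t1=trace.events["contact"])
print(an.oscillation_stats(pre, transient_ms=2000).ranges)
print(an.state_diagram(trace).pre_class)
post = trace.segment(t0=trace.events["removal"])
print(an.detect_cessation(post.t_ms, post.gamma))
```

prints (deterministically):

```
{'contact': 5219.8, 'removal': 5319.9, 'slow_full': 5519.9,
 'fast_ld_full_levator': 6454.5, 'fast_ld_full_depressor': 6681.4}
{'alpha': (-33.1, 31.1), 'beta': (-5.6, 34.5), 'gamma': (122.2, 174.5)}
LoopClass(label='triangular', vertex_count=3, confidence=1.0)
[(5320.0, 6201.0)]
```

The leg hits the obstacle at α = 15° after 5.2 s of established rhythm
(period ≈ 1.14 s), is silenced and held for 100 ms, and the fast
levator/depressor pools take 1.13 s / 1.36 s to re-recruit (rf = 2.27 and
2.72 at this obstacle position).  The pre-contact β–γ state diagram is the
triangle-like search loop, and after removal the γ oscillation ceases for
≈ 0.9 s — the leg bobs up and down in a stretched posture before full
search resumes.

The same runs are available from the shell:

```
legsearch simulate --preset tonic_b4 --po 15 --out trace.csv
legsearch sweep --po-range -15:25:5 --presets all --out summary.csv
legsearch analyze --trace trace.csv
legsearch dump-config --preset switch_b16
```

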