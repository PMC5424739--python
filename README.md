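# gazefuzz

Fuzzy-system target selection for NIR camera-based gaze trackers.

Gaze-based interaction lets people — in particular users with motor
disabilities — point at on-screen targets with their eyes. The hard part is
not *where* the user looks but *whether* they mean to select what they are
looking at: triggering on gaze position alone selects everything the eye
rests on (the "Midas touch" problem), while long dwell-time triggers are
slow and tiring. `gazefuzz` implements a multimodal alternative: three
short-window cues are extracted around each candidate fixation and fused in
a Mamdani-style fuzzy system whose defuzzified score drives the selection
decision.

## The method

**Segmentation.** Each NIR eye frame is segmented for the dark pupil and the
bright corneal glint: histogram (Otsu) thresholding → morphological cleaning
→ circular Hough transform for a rough circle, then a Chan–Vese level-set
refinement restricted to an adaptive mask around the rough circle,
minimizing

```
F(c_in, c_out, C) = μ·Length(C) + λ_in ∫_in |u−c_in|² + λ_out ∫_out |u−c_out|²
```

Pupil size is the pixel count inside the refined boundary (no ellipse fit —
real pupils are not elliptical), and the geometric centers are region
centroids.

**Feature 1 — pupil accommodation.** Intentional fixations are accompanied
by a transient pupil constriction. The smoothed, min-max-normalized
10-frame pupil-size window p is matched against a bank of constriction
templates q_i by `F1 = min_i Σ_j (p_j − q_ij)²` (lower = stronger evidence).

**Feature 2 — short-dwell gaze change.** The pupil center, compensated by
the glint center (cancelling head translation), maps to monitor coordinates
through a 4-corner bilinear calibration `G_x = ax + by + cxy + d`,
`G_y = ex + fy + gxy + h`. `F2 = Σ_{i=S}^{S+W−1} Δz_i` sums Euclidean
frame-to-frame gaze changes over the dwell window (lower = stiller).

**Feature 3 — gaze-target texture.** People fixate texture-rich content, so
the mean |response| of a 16-kernel real Gabor wavelet bank (4 orientations ×
4 scales) over a gaze-centered ROI of the monitor image scores the target
region (higher = more object-like).

**Fuzzy fusion.** Features are min-max normalized to [0,1] (F1, F2
inverted so high = selection-like), mapped through Low/High linear
membership functions (optionally fitted from labeled data by a
maximum-entropy criterion), fired through a fixed 8-rule table under MIN or
MAX inference, aggregated per output label, and defuzzified by FOM, MOM,
LOM, COG or BOA. The user is deemed to be selecting iff the score strictly
exceeds a threshold. Detection quality is reported as type I/II error
rates, EER and ROC curves.

## Worked example

```python
from gazefuzz import gen_session, gen_eye_frame, detect_pupil_and_glint, compute_eer
from gazefuzz.pipeline import score_session

# one synthetic NIR eye frame (noise sigma = 10) through the detector
frame, truth = gen_eye_frame(seed=1, noise_sigma=10)
det = detect_pupil_and_glint(frame)
print(f"pupil center: ({det.pupil_center[0]:.2f}, {det.pupil_center[1]:.2f})  "
      f"(truth (80.00, 60.00)),  area: {det.pupil_area} px")
print(f"glint center: ({det.glint_center[0]:.2f}, {det.glint_center[1]:.2f})  (truth (85.00, 55.00))")

# a 10-event session (5 selection / 5 non-selection) end to end
session = gen_session(n_events=10, seed=0)
scored = score_session(session)
for i, s in enumerate(scored):
    print(f"event {i}: label={s.truth}  score={s.score:.3f}")
r = compute_eer(scored)
print(f"EER = {r.eer_pct:.2f}% at threshold {r.threshold:.3f} "
      f"(type I {r.type1_pct:.2f}%, type II {r.type2_pct:.2f}%)")
```

prints

```
pupil center: (79.83, 60.17)  (truth (80.00, 60.00)),  area: 1464 px
glint center: (85.00, 55.00)  (truth (85.00, 55.00))
event 0: label=1  score=0.718
event 1: label=0  score=0.000
event 2: label=1  score=0.820
event 3: label=0  score=0.167
event 4: label=1  score=0.833
event 5: label=0  score=0.000
event 6: label=1  score=0.820
event 7: label=0  score=0.167
event 8: label=1  score=0.482
event 9: label=0  score=0.000
EER = 0.00% at threshold 0.167 (type I 0.00%, type II 0.00%)
```

The detector recovers the pupil center to ~0.2 px and the glint center to
~0.1 px under heavy sensor noise. Selection events score high (the H output
set dominates), casual fixations on blank screen regions score low (~0.17,
L set), and wandering-gaze events carry no fixation window and score 0 —
so a threshold anywhere between the classes classifies every event
correctly (EER 0%).

The same pipeline is available from the shell:

```bash
gazefuzz synth --events 20 --seed 1 --out session/
gazefuzz extract --session session/ --out features.csv
gazefuzz decide --features features.csv --out decisions.csv
gazefuzz evaluate --scores scores.csv --out eer.json --roc roc.csv
gazefuzz run --events 20 --seed 1 --out results/      # all of the above
```

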