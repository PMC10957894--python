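"""Event annotations: validation, inter-rater reliability, short-event
merging, and the scrambled-ratings null condition.

Two coders rate each movie event's semantic and social content 1-10;
Krippendorff's alpha below 0.75 flags the ratings for consensus
revision.  Events shorter than 3 s are merged into their successor with
averaged ratings before any time-course construction.
"""

import numpy as np

from natsemsoc import krippendorff_alpha, merge_short_events, scramble_ratings, validate_events
from natsemsoc import synthdata as sd

events, _ = sd.gen_events(350, seed=4)
report = validate_events(events)
print(f"validation: {'clean' if report.ok else report.violations}")

# a second coder: first coder's ratings plus bounded disagreement
rng = np.random.default_rng(5)
r1 = events["semantic"].to_numpy()
r2 = np.clip(r1 + rng.integers(-1, 2, len(r1)), 1, 10)
res = krippendorff_alpha(np.array([r1, r2], float), level="interval")
print(f"Krippendorff's alpha (semantic): {res.alpha:.3f} "
      f"-> needs consensus revision: {res.needs_revision}")

merged = merge_short_events(events, min_duration=3.0)
print(f"\nshort-event merging: {len(events)} -> {len(merged)} events "
      f"({(events['duration'] < 3).sum()} events under 3 s absorbed)")
print(f"post-merge durations: {merged['duration'].min():.1f}-"
      f"{merged['duration'].max():.1f} s, median {merged['duration'].median():.1f} s")

scrambled = scramble_ratings(merged, which="both", seed=6)
r = np.corrcoef(merged["semantic"], scrambled["semantic"])[0, 1]
print(f"\nscrambled-ratings null: correlation with true ratings r = {r:+.3f} "
      "(timing untouched, ratings permuted)")
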