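"""Event-bounded sliding-window predictors: factor sums, content-word
counts, and residualization on word quantity.

A 5 s window slides in 1 s steps inside each event (never across a
boundary), summing per-word values.  Factor series are residualized on
the total word count per window so they track word *properties*, not
speech rate; windows with no rated words are dropped rather than scored
zero.
"""

import numpy as np
import pandas as pd

from natsemsoc import merge_short_events, residualize, drop_empty
from natsemsoc import synthdata as sd
from natsemsoc.timecourse import content_word_counts, window_sums

lexicon, truth = sd.gen_lexicon(300, missing_rate=0.0, seed=7)
events, _ = sd.gen_events(100, seed=8)
merged = merge_short_events(events)
transcript = sd.gen_transcript(merged, lexicon, seed=9)
print(f"{len(merged)} events, {len(transcript)} transcript words")

social = truth.latents.set_index("word")["SocialImpact"].to_dict()
vals = transcript["word"].map(social).to_numpy(float)
keep = ~np.isnan(vals)
series = window_sums(
    pd.DataFrame({"onset": transcript["onset"][keep], "value": vals[keep]}), merged
)
counts = window_sums(
    pd.DataFrame({"onset": transcript["onset"], "value": np.ones(len(transcript))}),
    merged,
)
print(f"{len(series)} windows at 1 Hz; "
      f"{series.samples['empty'].sum()} contain no rated words")

resid = residualize(series, counts)
r_before = np.corrcoef(series.values, counts.values)[0, 1]
r_after = np.corrcoef(resid.values, counts.values)[0, 1]
print(f"correlation with word count: {r_before:+.3f} before, "
      f"{r_after:+.1e} after residualization")

final = drop_empty(resid)
print(f"{len(final)} windows kept after dropping empties")

cw = content_word_counts(transcript, merged)
print(f"content-word counts: mean {cw.values.mean():.1f} words/window "
      "(zero-count windows kept: a silent window is meaningful)")
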