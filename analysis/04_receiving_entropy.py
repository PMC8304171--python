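"""Receiving-zone entropy: how unpredictable is the reply to each origin zone?

For each origin zone, collects all (origin -> next stroke) pairs within
rallies and scores the destination distribution with the normalized Shannon
entropy, per match, then averages across matches.
"""

import numpy as np
from _common import study_corpus, write_json

from courtentropy import receiving_profile


def main() -> None:
    ds = study_corpus()
    mean_H, n_defined, per_match = receiving_profile(ds.matches)
    print("average receiving-zone entropy per origin zone:")
    for z in range(12):
        if n_defined[z]:
            print(f"  zone {z + 1:2d}: H = {mean_H[z]:.4f}  ({n_defined[z]} matches)")
        else:
            print(f"  zone {z + 1:2d}: undefined (no outgoing pairs)")
    hi, lo = int(np.nanargmax(mean_H)), int(np.nanargmin(mean_H))
    print(f"most unpredictable replies from zone {hi + 1} (H = {mean_H[hi]:.4f}); "
          f"most predictable from zone {lo + 1} (H = {mean_H[lo]:.4f})")
    out = write_json(
        "receiving_entropy.json",
        {
            "mean_H": [None if np.isnan(v) else float(v) for v in mean_H],
            "n_matches_defined": n_defined.tolist(),
        },
    )
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
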