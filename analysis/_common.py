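"""Shared setup for the analysis drivers: paths and the study corpus.

Every driver regenerates the same synthetic corpus deterministically from
CORPUS_SEED, so the scripts can run in any order.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from courtentropy import SyntheticConfig, generate_corpus  # noqa: E402

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
RESULTS = os.path.join(ROOT, "results")
SCRATCH = os.path.join(ROOT, "scratch")

CORPUS_SEED = 42
N_MATCHES = 259


def study_corpus():
    """The 259-match synthetic study corpus (deterministic)."""
    return generate_corpus(SyntheticConfig(n_matches=N_MATCHES, seed=CORPUS_SEED))


def write_json(name: str, payload: dict) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    path = os.path.join(RESULTS, name)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path
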