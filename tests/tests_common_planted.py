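"""Helper shared by attribution and acceptance tests: compare mean attribution
over planted-motif tokens against the background mean."""
from __future__ import annotations

import numpy as np

from lncmotif import attribution
from lncmotif.datasets import seq_to_kmers
from lncmotif.pipeline import PRIMARY_MOTIF


def planted_vs_background_means(model, positive_sequences, method, motif=PRIMARY_MOTIF):
    planted_scores, background_scores = [], []
    k = model.config.k
    for seq in positive_sequences:
        pos = seq.find(motif)
        assert pos != -1
        doc = seq_to_kmers(seq, k, source_id="probe")
        track = attribution.attribute(model, doc, method=method)
        scores = np.asarray(track.scores)
        lo = max(0, pos - k + 1)
        hi = min(len(scores), pos + len(motif))  # tokens overlapping the motif
        overlap = np.zeros(len(scores), dtype=bool)
        overlap[lo:hi] = True
        planted_scores.extend(scores[overlap])
        background_scores.extend(scores[~overlap])
    return float(np.mean(planted_scores)), float(np.mean(background_scores))
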