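#!/usr/bin/env python
"""Build per-subject feature matrices from the FC matrices.

Writes, under results/features/:
  * <measure>.features.tsv      — flattened upper-triangle FC features
                                  (the pipeline default), and
  * <measure>.node2vec.tsv      — node2vec-embedding concatenation features
                                  for comparison (every subject embedded
                                  with the same seed so vectors align).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fconn.cohort import read_cohort
from fconn.embedding import (
    Node2VecConfig,
    embed_graph,
    fc_flatten_features,
    fc_to_graph,
    subject_features,
)
from fconn.fc import read_fc_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"
MEASURES = ("PCC", "MIC", "eMIC")
SEED = 2023


def main() -> None:
    cohort = read_cohort(ROOT / "cohort")
    out = ROOT / "features"
    out.mkdir(parents=True, exist_ok=True)
    n2v = Node2VecConfig(seed=SEED)
    ids = [s.subject_id for s in cohort.subjects]
    for measure in MEASURES:
        flat, emb = [], []
        for sid in ids:
            fc = read_fc_matrix(ROOT / "fc" / f"{sid}.{measure}.tsv")
            flat.append(fc_flatten_features(fc))
            graph = fc_to_graph(fc, 1.0)
            emb.append(subject_features(embed_graph(graph, n2v, sid)))
        pd.DataFrame(np.vstack(flat), index=ids).to_csv(
            out / f"{measure}.features.tsv", sep="\t", header=False,
            float_format="%.17g")
        pd.DataFrame(np.vstack(emb), index=ids).to_csv(
            out / f"{measure}.node2vec.tsv", sep="\t", header=False,
            float_format="%.17g")
        print(f"{measure}: {len(ids)} subjects, "
              f"{len(flat[0])} flatten / {len(emb[0])} node2vec features")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
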