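#!/usr/bin/env python
"""Classify every tested candidate as reversible, persistent or absent by
combining the branaplam-vs-DMSO and washout-vs-DMSO significance calls,
then check the labels of planted responsive sites against the truth table.

Writes results/washout_labels.tsv.
"""

from pathlib import Path

import pandas as pd

from pseudoex.diffexpr import DEResult, classify_washout

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def _load(path):
    df = pd.read_csv(path, sep="\t")
    return [
        DEResult(r.feature_id, r.mean_expr, r.log2fc, r.t, r.p, r.adj_p)
        for r in df.itertuples()
    ]


def main() -> None:
    pre = _load(RESULTS / "de_branaplam.tsv")
    post = _load(RESULTS / "de_washout.tsv")
    ids = {r.feature_id for r in pre} & {r.feature_id for r in post}
    labels = classify_washout(
        [r for r in pre if r.feature_id in ids],
        [r for r in post if r.feature_id in ids],
    )
    out = pd.DataFrame({"feature_id": list(labels), "label": list(labels.values())})
    out.to_csv(RESULTS / "washout_labels.tsv", sep="\t", index=False)

    counts = out.label.value_counts().to_dict()
    print(f"washout labels: {counts}")

    truth = pd.read_csv(RESULTS / "truth_table.tsv", sep="\t")
    truth["feature_id"] = truth.apply(
        lambda r: f"{r.chrom}:{r.start}-{r.end}:{r.strand}", axis=1
    )
    merged = out.merge(truth, on="feature_id")
    called = merged[merged.label != "absent"]
    resp_called = called[called.responsive]
    ok = (
        (resp_called.persistent & (resp_called.label == "persistent"))
        | (~resp_called.persistent & (resp_called.label == "reversible"))
    ).sum()
    print(
        f"of {len(resp_called)} called responsive sites, {ok} carry the "
        f"planted reversibility label "
        f"({len(resp_called) - ok} misclassified)"
    )


if __name__ == "__main__":
    main()
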