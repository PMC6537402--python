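#!/usr/bin/env python
"""Statistical evaluation: permutation test, paired comparisons, motifs.

Tests whether the ensemble's per-sequence classification beats random
labeling (within-patient label permutations), compares per-patient AUCs
between channels with the Wilcoxon signed-rank test (Bonferroni over the
number of comparisons), and writes per-position residue-frequency
matrices for the high-confidence prediction groups.
"""

import argparse
import pickle
from pathlib import Path

import pandas as pd

from bcrml import evaluate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--stage", type=Path, default=ROOT / "scratch/per_sequence_stage.pkl")
    parser.add_argument("--permutations", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    if not args.stage.exists():
        raise SystemExit(f"{args.stage} not found — run 03_per_sequence_classifiers.py first")

    with open(args.stage, "rb") as fh:
        stage = pickle.load(fh)
    per_seq = stage["per_seq"]
    predictions = per_seq.probabilities.rename(columns={"p_ens": "prob"})

    perm_seq = evaluate.permutation_test(
        predictions, n_permutations=args.permutations, seed=args.seed
    )
    perm_clone = evaluate.permutation_test(
        predictions,
        n_permutations=args.permutations,
        seed=args.seed,
        group_col="clone_id",
    )
    print(
        f"permutation test (observed mean per-patient AUC {perm_seq.observed:.3f}):\n"
        f"  sequence-level shuffling p = {perm_seq.p_value:.4g}\n"
        f"  clone-level shuffling    p = {perm_clone.p_value:.4g} "
        f"(calibrated for clone-replicated rows)"
    )

    # paired comparison: ensemble vs each channel, Bonferroni over 4 tests
    channels = sorted(per_seq.channel_auc)
    print("\nWilcoxon signed-rank, ensemble vs channel (Bonferroni x4):")
    for channel in channels:
        patients = sorted(
            set(per_seq.ensemble_auc) & set(per_seq.channel_auc[channel])
        )
        p = evaluate.compare_paired_auc(
            [per_seq.ensemble_auc[q] for q in patients],
            [per_seq.channel_auc[channel][q] for q in patients],
            n_comparisons=len(channels),
        )
        print(f"  vs {channel}: adjusted p = {p:.4g}")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    records = [r for r, _ in stage["training"].labeled]
    probs = predictions["prob"].to_numpy()
    labels = predictions["label"].to_numpy()
    for group in ("correct-normal", "correct-tumor"):
        try:
            m = evaluate.motif_frequency_matrix(
                records, probs, labels, region="CDR3", group=group
            )
        except ValueError as exc:
            print(f"\nCDR3 motif {group}: {exc}")
            continue
        out = results / f"motif_CDR3_{group}.tsv"
        m.frequencies.round(4).to_csv(out, sep="\t")
        print(f"\nCDR3 motif {group}: {m.n_sequences} sequences -> {out}")


if __name__ == "__main__":
    main()
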