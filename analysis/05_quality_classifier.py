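"""Two-stage intrinsic-quality classifier: repeated Random-Forest variable
ranking on the stringent labels, then a CART rule on the non-stringent
labels, evaluated on the held-out donors and conditions."""
from pathlib import Path

from serumqc import GeneratorConfig
from serumqc.replication import classifier_replicate

OUT = Path("results/analysis")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rep = classifier_replicate(seed)
    print(f"candidate variables: {rep['n_variables']} "
          f"({rep['n_passing_pairs']} screened ratios + 4 sum ratios)")
    print(f"top variables: {', '.join(rep['top_variables'])}")
    print(f"rule: {rep['rule']}")
    print(f"misclassification: training {rep['train_rate']:.3f}, "
          f"test {rep['test_rate']:.3f}")
    print(f"wet ice all good: {rep['wet_all_good']}; "
          f"12 h RT fraction good: {rep['frac_rt12_good']:.2f}")
    import json
    (OUT / "classifier_summary.json").write_text(
        json.dumps({k: v for k, v in rep.items() if k != "tree_splits"}, default=str, indent=2)
    )


if __name__ == "__main__":
    main()
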