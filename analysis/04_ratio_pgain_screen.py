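"""All-pairs log-ratio mixed models with the p-gain screen, for the
handling and freeze-thaw schemes."""
from pathlib import Path

from serumqc import apply_qc, build_p150_panel, read_dataset
from serumqc.ratios import (
    fit_ratio_screen, pgain_threshold, ratio_alpha, ratio_table,
    screen_ratios, single_reference,
)

OUT = Path("results/analysis")


def main() -> None:
    ds = read_dataset(OUT / "concentrations.csv", OUT / "samples.csv", build_p150_panel())
    filtered, _ = apply_qc(ds)
    mets = filtered.panel.ids
    singles = single_reference(filtered, mets)
    rr = screen_ratios(fit_ratio_screen(filtered, mets, singles=singles))
    ratio_table(rr).to_csv(OUT / "ratio_models.csv", index=False)
    n_pass = sum(bool(r.passed_screen) for r in rr)
    print(f"handling: {n_pass}/{len(rr)} pairs pass "
          f"(p < {ratio_alpha(len(rr), 3):.3g}, p-gain > {pgain_threshold(len(rr), 3):.0f})")
    rr_ftc = screen_ratios(fit_ratio_screen(filtered, mets, scheme="ftc"))
    n_ftc = sum(bool(r.passed_screen) for r in rr_ftc)
    print(f"freeze-thaw: {n_ftc}/{len(rr_ftc)} pairs pass "
          f"(p-gain > {pgain_threshold(len(rr_ftc), 1):.0f}; expected none)")


if __name__ == "__main__":
    main()
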