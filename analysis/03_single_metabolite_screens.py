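"""Mixed-effects screens: handling (time, temperature, interaction) and
freeze-thaw cycles, Bonferroni-controlled, on the QC-retained metabolites."""
from pathlib import Path

from serumqc import apply_qc, build_p150_panel, read_dataset
from serumqc.association import (
    fit_ftc_screen, fit_handling_screen, results_table, screen_metabolites,
)

OUT = Path("results/analysis")


def main() -> None:
    ds = read_dataset(OUT / "concentrations.csv", OUT / "samples.csv", build_p150_panel())
    filtered, _ = apply_qc(ds)
    handl = fit_handling_screen(filtered, filtered.panel.ids)
    _, tiers = screen_metabolites(handl, "handling")
    results_table(handl, filtered.panel).to_csv(OUT / "handling_models.csv", index=False)
    tiers.to_csv(OUT / "handling_significant.csv", index=False)
    print(f"{len(tiers)} metabolites temperature-significant; tiers: "
          f"{tiers['tier'].value_counts().to_dict()}")
    up = (tiers.direction == '+').sum()
    print(f"directions: {up} up, {(tiers.direction == '-').sum()} down")
    ftc = fit_ftc_screen(filtered, filtered.panel.ids)
    _, ftc_sig = screen_metabolites(ftc, "ftc")
    results_table(ftc, filtered.panel).to_csv(OUT / "ftc_models.csv", index=False)
    print(f"freeze-thaw screen: {len(ftc_sig)} significant (expected none)")


if __name__ == "__main__":
    main()
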