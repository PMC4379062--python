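"""Apply the kit QC filters (pool CV < 25%, >= 50% of measurements above
3x the zero-sample mean) and report what survives."""
from pathlib import Path

from serumqc import apply_qc, build_p150_panel, read_dataset

OUT = Path("results/analysis")


def main() -> None:
    ds = read_dataset(OUT / "concentrations.csv", OUT / "samples.csv", build_p150_panel())
    filtered, report = apply_qc(ds)
    report.to_csv(OUT / "qc_report.csv")
    reasons = report.table.loc[~report.table.passed, "fail_reasons"].value_counts()
    print(f"retained {report.n_passed}/{len(ds.panel)} metabolites; "
          f"failures by reason: {reasons.to_dict()}")


if __name__ == "__main__":
    main()
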