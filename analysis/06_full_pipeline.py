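"""One-command replay of every stage via the pipeline orchestrator,
writing all artifacts and the run report under results/analysis/pipeline."""
from serumqc import RunConfig, run_pipeline

def main(seed: int = 1) -> None:
    report = run_pipeline(RunConfig(out_dir="results/analysis/pipeline", seed=seed))
    print(open("results/analysis/pipeline/report.md").read())

if __name__ == "__main__":
    main()
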