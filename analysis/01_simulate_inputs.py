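"""Generate the synthetic validation bundle every later stage consumes.

Emulates a validated comprehensive-panel study: 61 genes of exon targets
with splice padding and a small SegDup subset, a 5,000-variant
genotype-known truth set, an evaluation callset with planted 7% FP / 4% FN /
1% genotype-error structure, 1-plex (~301x) and 3-plex (~117x) depth tracks
with a depressed first exon, and four replicates spanning the variability
groupings.  Everything is written as plain text under results/sim/.
"""

from pathlib import Path

import yaml
import dataclasses

from panelval import io as pio
from panelval.simulate import (SimulationConfig, make_reference_panel,
                               simulate_depth, simulate_eval,
                               simulate_replicates, simulate_truth)

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"

CONFIG = SimulationConfig(seed=1, n_genes=61, n_truth_variants=5000,
                          fp_rate=0.07, fn_rate=0.04,
                          genotype_error_rate=0.01,
                          first_exon_depth_multiplier=0.1,
                          segdup_fraction=0.02, n_replicates=4)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = make_reference_panel(CONFIG)
    truth = simulate_truth(ref.targets, CONFIG)
    eval_calls = simulate_eval(truth, CONFIG)
    depth1 = simulate_depth(ref.targets, CONFIG, plex=1)
    depth3 = simulate_depth(ref.targets, CONFIG, plex=3)
    replicates = simulate_replicates(truth, CONFIG)

    pio.write_targets_bed(ref.targets, OUT / "targets.bed")
    pio.write_segdups_bed(ref.segdups, OUT / "segdups.bed")
    pio.write_vcf(truth, OUT / "truth.vcf")
    pio.write_vcf(eval_calls, OUT / "eval.vcf")
    pio.write_depth_tsv(depth1, OUT / "depth_1plex.tsv")
    pio.write_depth_tsv(depth3, OUT / "depth_3plex.tsv")
    pio.write_replicate_manifest(replicates, OUT / "replicates",
                                 OUT / "replicates.tsv")
    (OUT / "sim_config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(CONFIG)))

    print(f"targets: {len(ref.targets)} regions, "
          f"{ref.index.total_bases()} bases across {CONFIG.n_genes} genes")
    print(f"truth variants: {len(truth.calls)}; "
          f"eval calls: {len(eval_calls.calls)}; "
          f"segdup regions: {len(ref.segdups)}")
    print(f"replicates: {len(replicates)}; bundle written to {OUT}")


if __name__ == "__main__":
    main()
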