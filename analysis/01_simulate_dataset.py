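#!/usr/bin/env python
"""Generate the demo study: a ground-truthed synthetic bisulfite dataset.

Simulates 150 transcripts carrying 250 true m5C sites (two thirds NSUN2-,
one sixth NSUN6-contexts, one sixth unattributed), two biological replicates
of per-cytosine conversion evidence at over-dispersed ~50x coverage with a
0.3% conversion-failure rate and sparse structure-artifact reads, plus an
NSUN2-knockout condition.  Everything downstream (02-05) reads results/sim/.
"""

import os

from m5cpipe import io as mio
from m5cpipe.simulate import (SimConfig, simulate_depletion,
                              simulate_methylome, simulate_pileups,
                              simulate_transcriptome)
from m5cpipe.transcripts import write_bed12

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "sim")

CONFIG = SimConfig(seed=2024, n_transcripts=150, n_true_sites=250)


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    genome, models = simulate_transcriptome(CONFIG)
    genome, truth = simulate_methylome(genome, models, CONFIG)
    mio.write_fasta(genome, f"{OUT}/genome.fa")
    write_bed12(models, f"{OUT}/transcripts.bed12")
    truth.to_csv(f"{OUT}/truth.tsv", sep="\t", index=False)
    for i, rep in enumerate(simulate_pileups(genome, truth, CONFIG), start=1):
        mio.write_counts(rep.with_3c(), f"{OUT}/counts_wt_rep{i}.tsv")

    ko_truth = simulate_depletion(truth, "NSUN2", residual_factor=0.1)
    ko_truth.to_csv(f"{OUT}/truth_nsun2ko.tsv", sep="\t", index=False)
    ko_cfg = SimConfig(**{**CONFIG.__dict__, "seed": CONFIG.seed + 1})
    for i, rep in enumerate(simulate_pileups(genome, ko_truth, ko_cfg), start=1):
        mio.write_counts(rep.with_3c(), f"{OUT}/counts_nsun2ko_rep{i}.tsv")

    n_cyt = sum(s.count("C") for s in genome.values())
    print(f"simulated {len(models)} transcripts ({n_cyt} cytosines), "
          f"{len(truth)} true sites")
    print(truth.writer.value_counts().to_string())
    print(f"wild-type and NSUN2-KO evidence written to {os.path.normpath(OUT)}")


if __name__ == "__main__":
    main()
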