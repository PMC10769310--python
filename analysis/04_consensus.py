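#!/usr/bin/env python
"""Call strain-specific Tsu4 consensus sequences from filtered pileups.

Pileups exclude alignments below MAPQ 20 and bases below quality 20;
strains with normalized internal depth < 0.75 or breadth < 0.9 are removed
so consensus sequences are not biased toward the reference query.
"""

import shutil

import pandas as pd

from common import RESULTS, RUN_DIR, get_config, parse_seed
from retrotrace.workflow import run_stage

cfg = get_config(parse_seed(__doc__))
run_stage("consensus", cfg)

shutil.copy(RUN_DIR / "consensus" / "consensus_stats.tsv", RESULTS / "consensus_stats.tsv")
stats = pd.read_csv(RUN_DIR / "consensus" / "consensus_stats.tsv", sep="\t")
kept = stats.retained.sum()
print(f"{kept}/{len(stats)} strains passed the depth>=0.75 & breadth>=0.9 retention rule.")
print(stats.to_string(index=False))
print(f"Consensus FASTA -> {RUN_DIR}/consensus/consensus.fasta; stats -> {RESULTS}/consensus_stats.tsv")
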