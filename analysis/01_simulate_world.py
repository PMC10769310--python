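#!/usr/bin/env python
"""Simulate the two-species ground-truth world.

Plants a Ty4-like subfamily in species B and a Tsu4-like subfamily in
species A, transfers one Tsu4 lineage horizontally into a subclade of B,
and creates a Ty4-Tsu4-Ty4 recombinant inside that subclade; emits
genomes, 50x short reads, and read alignments for all 24 strains.
"""

import json
import shutil

from common import RESULTS, get_config, parse_seed
from retrotrace.workflow import run_stage

seed = parse_seed(__doc__)
cfg = get_config(seed)
run_stage("simulate", cfg)

sim = RESULTS.parent / "scratch" / "analysis_run" / "simulate"
meta = json.loads((sim / "scenario.json").read_text())
shutil.copy(sim / "presence_truth.tsv", RESULTS / "presence_truth.tsv")
shutil.copy(sim / "events.tsv", RESULTS / "event_log.tsv")

print(f"Simulated {len(meta['strains'])} strains across two species "
      f"(host divergence {meta['species_divergence']}).")
print(f"Planted HTT: Tsu4 from species {meta['donor_species']} into the "
      f"{len(meta['recipient_clade'])}-strain clade {meta['recipient_clade']} of species "
      f"{meta['recipient_species']}.")
print(f"Planted recombinant (breakpoints {meta['breakpoints']}) in strains "
      f"{meta['recomb_strains']}.")
print(f"Truth tables -> {RESULTS}/presence_truth.tsv, {RESULTS}/event_log.tsv")
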