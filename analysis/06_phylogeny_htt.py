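#!/usr/bin/env python
"""Build FLE trees and infer horizontal transfer.

Bootstrapped neighbor-joining trees of FLE internal regions (whole and
per-segment at the detected breakpoints), Dollo/Fitch presence-absence
parsimony on the host tree, and the TE-vs-host distance ratio test that
flags species pairs whose TE similarity is inconsistent with vertical
transmission.
"""

import json
import shutil

import pandas as pd

from common import RESULTS, RUN_DIR, get_config, parse_seed
from retrotrace.workflow import run_stage

cfg = get_config(parse_seed(__doc__))
run_stage("phylo", cfg)
run_stage("htt", cfg)

for name in ("segment_rf.tsv",):
    shutil.copy(RUN_DIR / "phylo" / name, RESULTS / name)
for name in ("dollo_events.tsv", "htt_flags.tsv"):
    shutil.copy(RUN_DIR / "htt" / name, RESULTS / name)
shutil.copy(RUN_DIR / "phylo" / "fle_tree_rooted.nwk", RESULTS / "fle_tree_rooted.nwk")

flags = pd.read_csv(RUN_DIR / "htt" / "htt_flags.tsv", sep="\t")
dollo = pd.read_csv(RUN_DIR / "htt" / "dollo_events.tsv", sep="\t")
meta = json.loads((RUN_DIR / "simulate" / "scenario.json").read_text())

print("HTT ratio test (min inter-species TE distance / host distance):")
print(flags.to_string(index=False) if len(flags) else "  no pairs flagged")
row = dollo[(dollo.subfamily == "Tsu4") & (dollo.species == meta["recipient_species"])]
print("\nDollo parsimony for Tsu4 within the recipient species:")
print(row.to_string(index=False))
print(f"\nPlanted recipient clade: {meta['recipient_clade']}")
print(f"Trees -> {RESULTS}/fle_tree_rooted.nwk; tables -> {RESULTS}/htt_flags.tsv, "
      f"{RESULTS}/dollo_events.tsv, {RESULTS}/segment_rf.tsv")
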