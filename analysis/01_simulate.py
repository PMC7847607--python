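"""Generate the study's synthetic inputs.

Writes three seeded scenarios under results/scenarios/: a planted 21-nt
PHAS locus (the positive case every later stage consumes), a noise-only
negative control, and a two-tissue RdDM scenario, each with its
ground-truth manifest and a ready-to-run pipeline config.
"""

import sys
from pathlib import Path

import yaml

from phasloc.seq_io import write_srna_library
from phasloc.simulate import (
    make_mutant_library,
    make_phas_scenario,
    make_rddm_scenario,
    planted_phased_sequences,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "scenarios"


def main() -> None:
    planted = make_phas_scenario(SEED)
    planted_dir = OUT / "planted"
    planted.write(planted_dir)
    mutant = make_mutant_library(
        planted.srna, 0.05, SEED + 1, planted_phased_sequences(planted)
    )
    write_srna_library(mutant, planted_dir / "srna_mutant.tsv")
    config = {
        "transcripts": "transcripts.fasta",
        "srna_libraries": [{"path": "srna.tsv", "name": "wt"}],
        "degradome_libraries": [{"path": "degradome.tsv", "name": "deg1"}],
        "mutant_libraries": {21: {"path": "srna_mutant.tsv", "name": "osdcl4"}},
        "params": {"k_values": [21]},
    }
    with open(planted_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    print(
        f"planted locus: anchor {planted.manifest['anchor']}, region "
        f"{planted.manifest['region_start']}-{planted.manifest['region_end']}, "
        f"cleavage {planted.manifest['cleavage_site']}"
    )

    noise = make_phas_scenario(SEED + 1000, planted=False)
    noise.write(OUT / "noise_only")
    print(f"noise-only control: {noise.srna.total_count} reads, no locus")

    rddm = make_rddm_scenario(SEED)
    rddm.write(OUT / "rddm")
    print(
        f"rddm scenario: {len(rddm.manifest['planted_hits'])} planted "
        f"promoter hits on {rddm.manifest['promoter']}"
    )


if __name__ == "__main__":
    main()
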