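#!/usr/bin/env python
"""Generate the synthetic two-condition m6A-RIP study used by all analyses.

Writes gene models (GTF), the planted-peak truth table and a DE table with
planted direct effects under results/sim/; the bulky per-base IP/input
coverage tracks of both conditions go to scratch/sim_tracks/ (they are
byte-identical reproducible from SEED, so downstream drivers simply
regenerate them instead of parsing the TSVs).
"""

from pathlib import Path

from m6akit.annotation import write_gtf
from m6akit.synthetic import SimConfig, simulate_conditions, simulate_de
from m6akit.tracks import write_tracks_tsv

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "sim"
TRACKS = ROOT / "scratch" / "sim_tracks"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    TRACKS.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    control, silenced, truth = simulate_conditions(cfg)
    write_gtf(control.models.values(), OUT / "models.gtf")
    write_tracks_tsv(control.ip_tracks, TRACKS / "control_ip.tsv")
    write_tracks_tsv(control.input_tracks, TRACKS / "control_input.tsv")
    write_tracks_tsv(silenced.ip_tracks, TRACKS / "silenced_ip.tsv")
    write_tracks_tsv(silenced.input_tracks, TRACKS / "silenced_input.tsv")
    truth.to_csv(OUT / "peak_truth.tsv", sep="\t", index=False)
    de = simulate_de(cfg, truth, control.models)
    de.to_csv(OUT / "de_table.tsv", sep="\t", index=False)
    n_classes = truth["peak_class"].value_counts().to_dict()
    print(f"simulated {len(control.models)} genes, {len(truth)} planted peaks")
    print(f"planted peak classes: {n_classes}")
    print(f"tables under {OUT}; coverage tracks under {TRACKS}")


if __name__ == "__main__":
    main()
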