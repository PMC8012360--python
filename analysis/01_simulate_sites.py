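#!/usr/bin/env python
"""Simulate the synthetic GR ChIP-seq experiment with planted truth.

Generates a random genome, plants 50 motif-configured peak windows per
occupancy cluster (C1-C4) following the default class composition, draws
negative-binomial tag counts from the receptor templates, builds an
accessible-region pool, and writes everything (plus the truth table and
the synthetic motif models) under results/synthetic/.
"""

import argparse
from pathlib import Path

from grescan import motifs as mot
from grescan import peaks as pk
from grescan import synthetic as syn


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-per-cluster", type=int, default=50)
    ap.add_argument("--outdir", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    plan = syn.default_site_plan(args.n_per_cluster)
    n_sites = sum(c for per in plan.values() for c in per.values())
    n_extra = 2 * n_sites  # accessible background beyond the peaks
    spec = syn.SyntheticSpec(
        genome_length=n_sites * 520 + n_extra * 900 + 2000,
        n_sites_per_class=plan,
        seed=args.seed,
    )
    genome = syn.gen_genome(spec)
    peaks, truth, genome = syn.plant_sites(genome, spec)
    cluster_of = dict(zip(truth["site_id"], truth["cluster_template"]))
    syn.gen_tag_counts(peaks, cluster_of, seed=args.seed + 10)
    accessible = syn.gen_accessible_bed(
        len(genome), peaks, n_extra=n_extra, seed=args.seed + 20, chrom=spec.chrom
    )

    syn.write_fasta({spec.chrom: genome}, out / "genome.fa")
    pk.write_peaks(peaks, out / "peaks.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    syn.write_bed(accessible, out / "accessible.bed")
    motifs = syn.default_motif_set()
    mot.write_motif_file(
        [motifs[k] for k in ("full_well", "full_degen", "half")],
        out / "motifs.motif",
    )

    by_class = truth["planted_class"].value_counts().to_dict()
    print(f"genome: {len(genome):,} bp ({spec.chrom})")
    print(f"peaks:  {len(peaks)} across clusters "
          f"{sorted(set(cluster_of.values()))}")
    print(f"planted classes: {by_class}")
    print(f"accessible pool: {len(accessible)} intervals")
    print(f"wrote genome.fa, peaks.tsv, truth.tsv, accessible.bed, "
          f"motifs.motif to {out}")


if __name__ == "__main__":
    main()
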