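"""Fixed-width peak merging and chromatin-derived gene activity scores.

Builds the merged non-overlapping 500-bp peak set from per-cluster pseudo-bulk
candidate calls by iterative overlap merging, counts Tn5 insertions in peaks,
and computes distance-weighted gene activity scores (weight e^(-|d|/5000)+e^-1
within 100 kb of the TSS, gene-length factor 1..5, scaled to 10,000, log2).

Usage: python analysis/03_atac_features.py [--seed 1] [--out results]
"""

import argparse
import logging
from pathlib import Path

from sfmultiome import atac
from sfmultiome.config import AnalysisConfig
from sfmultiome.io import write_bed, write_count_matrix
from sfmultiome.pipeline import gene_score_rank_correlation
from sfmultiome.simulate import SimulationDesign, simulate_multiome


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = AnalysisConfig(seed=args.seed)
    sim = simulate_multiome(SimulationDesign(seed=args.seed))

    merged = atac.iterative_overlap_merge(sim.data.candidate_peaks)
    write_bed(merged, args.out / "merged_peaks.bed")
    peak_counts = atac.count_fragments_in_peaks(
        sim.data.fragments, merged, cell_ids=sim.data.metadata["cell_id"].tolist()
    )
    write_count_matrix(peak_counts, args.out / "peak_counts")

    scores = atac.gene_activity_scores(sim.data.tiles, sim.data.genes, cfg)
    write_count_matrix(scores, args.out / "gene_scores")
    rho = gene_score_rank_correlation(scores, sim.data.metadata, sim.truth)

    n_cand = sum(len(f) for reps in sim.data.candidate_peaks.values()
                 for f in reps.values())
    print(f"{n_cand} candidate peak calls -> {len(merged)} merged fixed-width peaks")
    print(f"peak count matrix: {peak_counts.shape[0]} peaks x "
          f"{peak_counts.shape[1]} cells "
          f"({peak_counts.values.sum():.0f} insertions in peaks)")
    print(f"gene activity vs planted promoter accessibility: "
          f"rank correlation {rho:.3f}")


if __name__ == "__main__":
    main()
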