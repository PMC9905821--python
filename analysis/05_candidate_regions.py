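"""Call candidate regions from both scans and intersect them.

Turns the delta(SNP-index) and ED^4 tracks into above-threshold regions,
intersects the two sets into the common candidate regions, and checks them
against the simulated truth (the causal marker positions written by
01_simulate_cross.py) — the narrowing step that, on the real data, shrank a
multi-megabase QTL to a sub-100-Kb interval.
"""

from pathlib import Path

import pandas as pd

from cottonbsa import regions as rg
from cottonbsa import stats

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "simulated"
RESULTS = ROOT / "results"


def main() -> None:
    tracks_path = SCRATCH / "tracks.tsv"
    if not tracks_path.exists():
        raise SystemExit("run analysis/04_bsa_scan.py first")
    tracks = pd.read_csv(tracks_path, sep="\t", dtype={"chrom": str})
    truth = pd.read_csv(SCRATCH / "truth.tsv", sep="\t", dtype={"chrom": str})

    thresholds = stats.track_thresholds(tracks)
    delta = rg.call_regions(tracks, thresholds["abs_delta_snp_index"], source="delta")
    ed = rg.call_regions(tracks, thresholds["ED4"], source="ED")
    common = rg.count_snps_in_regions(tracks, rg.intersect_region_sets(delta, ed))

    frames = []
    for name, rs in (("delta", delta), ("ED", ed), ("common", common)):
        f = rg.regions_to_frame(rs)
        f.insert(0, "scan", name)
        frames.append(f)
    all_regions = pd.concat(frames, ignore_index=True)

    major = truth.loc[truth["additive"].abs().idxmax()]
    major_pos = int(major["marker_pos"])
    hit = any(
        r.chrom == major["chrom"] and r.start <= major_pos <= r.end for r in common
    )

    RESULTS.mkdir(exist_ok=True)
    all_regions.to_csv(RESULTS / "05_candidate_regions.tsv", sep="\t", index=False)
    rg.regions_to_bed(common).to_csv(
        RESULTS / "05_common_regions.bed", sep="\t", index=False, header=False
    )
    print(all_regions.to_string(index=False))
    total_common = sum(r.length for r in common)
    print(
        f"\n{len(delta)} delta regions and {len(ed)} ED regions intersect to "
        f"{len(common)} common regions totalling {total_common/1e6:.2f} Mb"
    )
    print(
        f"major causal locus {major['chrom']}:{major_pos} "
        f"{'IS' if hit else 'is NOT'} contained in the common candidate set"
    )


if __name__ == "__main__":
    main()
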