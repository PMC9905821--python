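"""Parameter recovery and null specificity of the full pipeline.

Runs seeded replicates of the complete simulate -> bulks -> pooled counts ->
scans -> thresholds -> regions -> intersection analysis at the reference
settings and reports (a) how often the common candidate set contains the
causal locus, and (b) how often, with no causal locus at all, drift alone
produces a common region covering more than 10% of the genome.
"""

from pathlib import Path

import pandas as pd

from cottonbsa.recovery import null_experiment, recovery_experiment

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

N_REPLICATES = 50


def main(seed: int = 1) -> None:
    rec = recovery_experiment(n_replicates=N_REPLICATES, base_seed=seed)
    nul = null_experiment(n_replicates=N_REPLICATES, base_seed=seed)

    rows = [
        {
            "experiment": "causal locus present",
            "n_replicates": N_REPLICATES,
            "metric": "recovery rate (causal position in common set)",
            "value": rec["recovery_rate"],
        },
        {
            "experiment": "null (no causal locus)",
            "n_replicates": N_REPLICATES,
            "metric": "rate of common regions spanning >10% of genome",
            "value": nul["large_region_rate"],
        },
    ]
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "07_recovery_experiment.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(
        f"\nrecovery {rec['recovery_rate']:.0%} over {N_REPLICATES} replicates; "
        f"null false-localisation {nul['large_region_rate']:.0%}"
    )


if __name__ == "__main__":
    main()
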