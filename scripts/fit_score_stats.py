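"""Fit and cache the gapped local-alignment score statistics (lambda, K)
shipped as package data.

Run from the repository root:

    python scripts/fit_score_stats.py

Writes src/domainmine/data/score_stats.json. The fit is a seeded Monte-Carlo
moment-match of a Gumbel to optimal Smith-Waterman scores of random
amino-acid sequence pairs; see domainmine.search.fit_score_stats.
"""

import json
from pathlib import Path

from domainmine.search import fit_score_stats

OUT = Path(__file__).resolve().parent.parent / "src" / "domainmine" / "data" / "score_stats.json"

SCHEMES = [("BLOSUM62", 11, 1)]


def main():
    entries = []
    for matrix, go, ge in SCHEMES:
        stats = fit_score_stats(matrix, go, ge, n_pairs=400, length=200, seed=271828)
        entries.append(
            {
                "matrix": matrix,
                "gap_open": go,
                "gap_extend": ge,
                "lambda": stats.lam,
                "K": stats.K,
                "method": "moment-matched Gumbel over Smith-Waterman scores of 400 random length-200 uniform-background pairs",
                "seed": 271828,
            }
        )
        print(f"{matrix}/{go}/{ge}: lambda={stats.lam:.4f} K={stats.K:.4g}")
    OUT.write_text(json.dumps(entries, indent=2) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
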