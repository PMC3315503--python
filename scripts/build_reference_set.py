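"""Regenerate the miniature synthetic reference sets shipped as package data.

Run from the repository root:

    python scripts/build_reference_set.py

Writes {ks,c}_reference.synthetic.{faa,tsv,afa} into src/domainmine/data/.
The sets are synthetic class-structured families (see domainmine.synthetic)
carrying the real KS/C domain-class taxonomy and example-product metadata;
they stand in for a curated database of experimentally characterized pathway
domains, which cannot be redistributed with the package.
"""

from pathlib import Path

from domainmine.reference_db import write_reference_db
from domainmine.synthetic import simulate_reference_family

DATA = Path(__file__).resolve().parent.parent / "src" / "domainmine" / "data"

# fixed generation seeds; domain lengths approximate real KS (~400 aa) and
# C (~300 aa after trimming to the conserved core) tag sizes
SPECS = {
    "KS": dict(domain_type="KS", members_per_class=3, domain_length=400, seed=20120329),
    "C": dict(domain_type="C", members_per_class=3, domain_length=300, seed=20120330),
}


def main():
    for key, spec in SPECS.items():
        db, newick = simulate_reference_family(**spec)
        prefix = key.lower()
        write_reference_db(
            db,
            DATA / f"{prefix}_reference.synthetic.faa",
            DATA / f"{prefix}_reference.synthetic.tsv",
            DATA / f"{prefix}_reference.synthetic.afa",
        )
        (DATA / f"{prefix}_reference.synthetic.nwk").write_text(newick + "\n")
        print(f"{key}: {len(db)} domains, {db.alignment.n_columns} columns")


if __name__ == "__main__":
    main()
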