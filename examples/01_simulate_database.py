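"""Generate a synthetic clade-annotated marker-gene database.

Builds a two-clade database with one discriminative primer pair planted
into clade C01 (non-targets carry >= 4 mismatches in each binding site)
and writes it as FASTA + annotation TSV.
"""

from pathlib import Path

from cladeqpcr import FixtureSpec, PlantedSite, generate_clade_db, write_database

spec = FixtureSpec(
    n_clades=2,
    seqs_per_clade=5,
    seq_length_bp=260,
    intra_clade_substitution_rate=0.08,
    inter_clade_divergence=65,
    planted_sites=[
        PlantedSite(
            clade="C01",
            forward_coord=60,
            forward_seq="TGCAGGTCAACGTTCAG",
            reverse_coord=180,
            reverse_seq="ACGTTCAGGCATCTGAC",
            min_nontarget_mismatches=4,
        )
    ],
    seed=7,
)

db = generate_clade_db(spec)
out = Path("scratch/example_db")
out.mkdir(parents=True, exist_ok=True)
write_database(db, out / "ref.fasta", out / "clades.tsv")

print(f"records: {len(db)}  clades: {sorted(db.clades)}")
print(f"wrote {out}/ref.fasta and {out}/clades.tsv")
print("Each C01 sequence carries the planted primer sites verbatim; every")
print("C02 sequence differs from them by at least 4 substitutions per site.")
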