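"""Regenerate the bundled synthetic trinucleotide occurrence tables.

The tables under src/sigrefit/data/ are synthetic stand-ins for territory
count tables: they emulate the gross composition of a mammalian whole
genome (AT-rich, strongly CpG-depleted) and of a protein-coding exome
(more GC-rich, weaker CpG depletion) from independent-base frequencies
with a CpG suppression factor, scaled to plausible territory sizes.  They
are NOT counts from any real reference build; for real analyses derive a
table from your reference FASTA with sigrefit.catalog.tri_counts_from_fasta.

Run from the repository root:  python scripts/make_tri_count_tables.py
"""

from pathlib import Path

from sigrefit.contexts import PYRIMIDINE_TRIPLETS

OUT = Path(__file__).resolve().parent.parent / "src" / "sigrefit" / "data"

TERRITORIES = {
    # name: (GC content, CpG depletion factor, total positions both strands collapsed)
    "genome": (0.41, 0.22, 2_900_000_000),
    "exome": (0.50, 0.70, 33_000_000),
}


def base_freqs(gc: float) -> dict[str, float]:
    return {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, (gc, cpg_factor, total) in TERRITORIES.items():
        f = base_freqs(gc)
        raw = {}
        for tri in PYRIMIDINE_TRIPLETS:
            w = f[tri[0]] * f[tri[1]] * f[tri[2]]
            # CpG suppression: collapsed pyrimidine-centered triplets carry a
            # CpG when the central C is followed by G, or preceded by C when
            # the central base is G on the other strand (= central C preceded
            # by C's complement... on the collapsed triplet: X C G and C G X
            # both collapse to triplets with "CG" visible).
            if "CG" in tri:
                w *= cpg_factor
            raw[tri] = w
        scale = total / sum(raw.values())
        path = OUT / f"tri_counts_{name}_synthetic.tsv"
        with open(path, "w") as fh:
            fh.write("trinucleotide\tcount\n")
            for tri in PYRIMIDINE_TRIPLETS:
                fh.write(f"{tri}\t{int(round(raw[tri] * scale))}\n")
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
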