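"""Pooled zone strike distribution of the corpus and its standard entropy.

Which of the 12 court zones do players actually hit from?  Tallies every
stroke of the corpus, reports the per-zone percentages (the four corners
dominate by construction of the generator, as in elite match play) and the
normalized Shannon entropy of the pooled distribution.
"""

from _common import study_corpus, write_json

from courtentropy import standard_entropy, zone_pdf


def main() -> None:
    ds = study_corpus()
    pdf = zone_pdf(ds.matches)
    h = standard_entropy(pdf)
    pct = 100.0 * pdf.probabilities
    order = pct.argsort()[::-1]
    print("zone share of all strokes (descending):")
    for z in order:
        print(f"  zone {z + 1:2d}: {pct[z]:5.2f} %")
    corners = pct[[0, 3, 8, 11]].sum()
    print(f"four corners together: {corners:.1f} % of {pdf.total} strokes")
    print(f"pooled standard entropy H = {h.H:.4f} (1 = no positional preference)")
    out = write_json(
        "zone_distribution.json",
        {
            "counts": pdf.counts.tolist(),
            "percent": pct.tolist(),
            "corner_percent": float(corners),
            "pooled_standard_entropy": h.H,
            "total_strokes": pdf.total,
        },
    )
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
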