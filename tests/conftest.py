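import numpy as np
import pandas as pd
import pytest

from neuromat import trend as tr


def make_de_tables(genes, values):
    """Build the four-comparison DETable mapping from per-gene tuples.

    ``values[comparison]`` is a list of (logFC, fdr) per gene; pvalue is
    set equal to fdr (the classifier only reads logFC and fdr).
    """
    out = {}
    for comp in tr.COMPARISONS:
        lfc, fdr = zip(*values[comp])
        out[comp] = tr.DETable(
            comparison=comp,
            table=pd.DataFrame(
                {"logFC": lfc, "pvalue": fdr, "fdr": fdr}, index=list(genes)
            ),
        )
    return out


def random_de_tables(rng, n_genes):
    """Random logFC/FDR tables covering both sides of every rule boundary."""
    genes = [f"g{i}" for i in range(n_genes)]
    values = {}
    for comp in tr.COMPARISONS:
        lfc = rng.normal(0, 1.5, n_genes)
        fdr = rng.uniform(0, 0.12, n_genes)  # dense around the 0.05 boundary
        values[comp] = list(zip(lfc, fdr))
    return genes, make_de_tables(genes, values)


@pytest.fixture
def small_timecourse():
    """Tiny deterministic expression time course: 4 genes x DMSO d25..d100, n=2."""
    genes = ["up1", "down1", "flat1", "flat2"]
    samples = []
    counts = {}
    base = {"up1": 50, "down1": 400, "flat1": 100, "flat2": 100}
    mult = {"up1": [1, 2, 4, 8], "down1": [1, 0.5, 0.25, 0.125], "flat1": [1] * 4, "flat2": [1] * 4}
    for i, tp in enumerate(["d25", "d50", "d75", "d100"]):
        for rep in (1, 2):
            name = f"DMSO_{tp}_r{rep}"
            samples.append((name, tp, "DMSO", rep))
            counts[name] = [int(base[g] * mult[g][i]) + rep for g in genes]
    counts_df = pd.DataFrame(counts, index=genes)
    meta = pd.DataFrame(samples, columns=["sample", "timepoint", "treatment", "replicate"]).set_index("sample")
    lengths = pd.Series([2000, 1000, 1500, 3000], index=genes, name="length_bp")
    return tr.ExpressionTimecourse(counts=counts_df, gene_lengths=lengths, samples=meta)
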