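import numpy as np
import pytest

from hsescan import synthetic_data as sd


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic genome bundle written to disk: 45 genes, 600 bp
    promoters, one planted HSE per gene, plus DE table and term map."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = sd.EffectConfig(n_genes=45, promoter_length=600)
    genome = sd.simulate_genome(cfg, seed=7)
    paths = genome.write(out)
    de, truth = sd.simulate_expression(genome.ledger, cfg, seed=7)
    de_path = out / "de_table.tsv"
    de.to_csv(de_path, sep="\t", index=False)
    term_map, _ = sd.simulate_annotation(genome.ledger["gene_id"], 12, seed=3)
    tm_path = out / "term_map.tsv"
    sd.write_term_map(term_map, tm_path)
    return {
        "cfg": cfg,
        "genome": genome,
        "paths": paths,
        "de": de,
        "de_path": de_path,
        "truth": truth,
        "term_map": term_map,
        "term_map_path": tm_path,
        "out": out,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
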