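import pytest

from inversepv import DrugLexicon, SimConfig, generate_cases, write_faers_tables


@pytest.fixture(scope="session")
def messy_cfg() -> SimConfig:
    """A small but fully messy reporting system: an inverse-signal drug,
    brand/salt/case name variants, a combination product, duplicates."""
    return SimConfig(
        n_cases=4000,
        n_drugs=4,
        exposure_prob=0.12,
        baseline_event_prob=0.1,
        planted_or=(0.2, 1.0, 1.0, 1.0),
        duplicate_fraction=0.2,
        name_variants=(
            ("DRUG_0000", "drug_0000 HCL", "Zeronex 20MG TABLET"),
            ("DRUG_0001", "DRUG_0001 INJECTION"),
            ("DRUG_0002", "drug_0002  CALCIUM"),
            ("DRUG_0003",),
        ),
        combo_products=(("DRUG_0002 + DRUG_0003", (2, 3)),),
        n_noise_events=2,
        seed=20260921,
    )


@pytest.fixture(scope="session")
def messy_dataset(messy_cfg, tmp_path_factory):
    """Generated rows + ground truth, written out, with a matching lexicon."""
    rows, truth = generate_cases(messy_cfg)
    directory = tmp_path_factory.mktemp("faers")
    write_faers_tables(rows, directory)
    lexicon = DrugLexicon(messy_cfg.default_lexicon_entries())
    return {
        "cfg": messy_cfg,
        "rows": rows,
        "truth": truth,
        "dir": directory,
        "lexicon": lexicon,
    }
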