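import numpy as np
import pandas as pd
import pytest

import splicebalance as sb


@pytest.fixture(scope="session")
def small_cohort():
    """A mixed-effect cohort shared by read-only tests."""
    cfg = sb.CohortConfig(
        n_genes=80,
        exon_count_range=(2, 8),
        groups={"basal": 20, "NBT": 9},
        affected_group="basal",
        frac_de_only=0.1,
        frac_si_only=0.1,
        frac_both=0.05,
        noise_sd=0.3,
        seed=11,
    )
    return sb.generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted effects at all."""
    cfg = sb.CohortConfig(
        n_genes=300,
        exon_count_range=(2, 6),
        groups={"a": 15, "b": 15},
        affected_group="a",
        frac_de_only=0.0,
        frac_si_only=0.0,
        frac_both=0.0,
        noise_sd=0.3,
        seed=21,
    )
    return sb.generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    """The small cohort serialized to TSV."""
    directory = tmp_path_factory.mktemp("cohort")
    sb.write_dataset(*small_cohort, directory)
    return directory


@pytest.fixture()
def tiny_annotation():
    """Three genes: 2 + 3 + 1 probes."""
    rows = [
        ("gA:E00", "gA", 0), ("gA:E01", "gA", 1),
        ("gB:E00", "gB", 0), ("gB:E01", "gB", 1), ("gB:E02", "gB", 2),
        ("gC:E00", "gC", 0),
    ]
    annot = pd.DataFrame(rows, columns=["probe_id", "gene_id", "exon_index"])
    annot["chrom"] = "chrS"
    annot["start"] = np.arange(len(annot)) * 250
    annot["end"] = annot["start"] + 150
    annot["strand"] = "+"
    return annot.set_index("probe_id")
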