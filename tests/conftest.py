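import logging

import pandas as pd
import pytest

from varburden import datasets
from varburden.io import (
    write_baseline_table,
    write_carrier_counts,
    write_variant_table,
)

logging.getLogger("varburden").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def study_records():
    return datasets.study_variant_records()


@pytest.fixture(scope="session")
def validation_records():
    return datasets.validation_variant_records()


@pytest.fixture(scope="session")
def baseline_rows():
    return datasets.baseline_rows()


@pytest.fixture()
def fixture_dir(tmp_path, study_records, validation_records, baseline_rows):
    """On-disk copies of the reference fixtures in the documented dialects."""
    write_variant_table(study_records, tmp_path / "study.tsv")
    write_variant_table(validation_records, tmp_path / "validation.tsv")
    controls = pd.DataFrame(
        [
            {"class_label": label, "cohort": "controls", "carriers": a, "total": n}
            for label, (a, n) in datasets.control_carrier_counts().items()
        ]
    )
    write_carrier_counts(controls, tmp_path / "controls.tsv")
    write_baseline_table(baseline_rows, tmp_path / "baseline.tsv")
    return tmp_path
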