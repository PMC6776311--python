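import pandas as pd
import pytest

import scatniche as sn


@pytest.fixture(scope="session")
def table3_collection() -> sn.ScatCollection:
    return sn.table3_fixture()


@pytest.fixture(scope="session")
def occurrence(table3_collection) -> sn.scat_data.OccurrenceTable:
    return sn.tabulate_occurrences(table3_collection)


@pytest.fixture(scope="session")
def prey_ref() -> sn.PreyReference:
    return sn.packaged_prey_reference()


@pytest.fixture
def scats_csv(tmp_path):
    """Write rows (scat_id, river, year, taxon[, contaminated]) to a CSV."""

    def _write(rows, columns=("scat_id", "river", "year", "taxon")):
        path = tmp_path / "scats.csv"
        pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
        return path

    return _write
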