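import pytest

from mirank.ingest import load_table_fixtures


@pytest.fixture(scope="session")
def fixture_matrix():
    """Packaged raw + processed presence tables, loaded once."""
    return load_table_fixtures()


def make_ranking_file(path, rows, header="study\tproduct\trank\tmirna\ttie"):
    """Write a rankings TSV from (study, product, rank, mirna, tie) tuples."""
    lines = [header] + ["\t".join(str(c) for c in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
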