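import pytest

from aptaselect import datasets


@pytest.fixture(scope="session")
def gen1():
    return datasets.load_generation(1)


@pytest.fixture(scope="session")
def gen2():
    return datasets.load_generation(2)


@pytest.fixture(scope="session")
def gen2_parents(gen1):
    return [
        gen1.sequence_by_name(name) for name in datasets.GENERATION2_PARENTS
    ]


def vienna_text(table) -> str:
    """Serialize a generation table as a Vienna structures file."""
    lines = []
    for _, row in table.frame.iterrows():
        lines.append(f">{row['name']}")
        lines.append(row["sequence"])
        lines.append(f"{row['dotbracket']} ({row['mfe']})")
    return "\n".join(lines) + "\n"


def scores_tsv(table) -> str:
    lines = ["name\tzdock\tzrank"]
    for _, row in table.frame.iterrows():
        lines.append(f"{row['name']}\t{row['zdock']}\t{row['zrank']}")
    return "\n".join(lines) + "\n"
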