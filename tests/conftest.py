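import pytest

from strepdelim import load_packaged_table, GeneAlignmentSet


@pytest.fixture(scope="session")
def packaged():
    return load_packaged_table()


def _write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


@pytest.fixture
def gene_fastas(tmp_path):
    """Five tiny aligned gene files for three strains.

    Strain s2 differs from s1 by one A->G transition in atpD; strain s3
    additionally carries one A->T transversion in gyrB and a gap in recA.
    """
    lengths = {"atpD": 30, "gyrB": 45, "recA": 30, "rpoB": 60, "trpB": 30}
    base = {g: ("ACGTTG" * 20)[: n] for g, n in lengths.items()}
    strains = {
        "s1": dict(base),
        "s2": dict(base),
        "s3": dict(base),
    }
    strains["s2"]["atpD"] = "G" + base["atpD"][1:]          # A->G transition
    strains["s3"]["atpD"] = "G" + base["atpD"][1:]
    strains["s3"]["gyrB"] = "T" + base["gyrB"][1:]          # A->T transversion
    strains["s3"]["recA"] = "-" + base["recA"][1:]          # gap -> excluded
    paths = {}
    for gene in lengths:
        p = tmp_path / f"{gene}.fna"
        _write_fasta(p, {s: strains[s][gene] for s in strains})
        paths[gene] = p
    return paths
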