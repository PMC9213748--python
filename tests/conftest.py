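import pytest

from mitocompare.mito_io import GeneFeature, MitoGenome
from mitocompare.simulate import SimConfig, generate_ancestor


@pytest.fixture(scope="session")
def default_ancestor():
    """Default synthetic mitogenome (17 features, canonical order), seed 7."""
    return generate_ancestor(SimConfig(seed=7))


@pytest.fixture
def tiny_genome():
    seq = "ATGGTTTAA" + "CCCC" + "ATGAAATAG" + "TT"
    feats = [
        GeneFeature("cox1", "CDS", 0, 9, 1),
        GeneFeature("ND3", "CDS", 13, 22, 1),
    ]
    return MitoGenome("tiny", seq, circular=True, features=feats)


def make_genbank(tmp_path, body_features, seq, topology="circular", name="test.gb"):
    """Write a minimal but well-formed GenBank flat file."""
    origin_lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60].lower()
        spaced = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        origin_lines.append(f"{i + 1:>9} {spaced}")
    lines = [
        f"LOCUS       testrec     {len(seq)} bp    DNA     {topology} INV 01-JAN-2024",
        "DEFINITION  synthetic fixture record.",
        "ACCESSION   testrec",
        "VERSION     testrec.1",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(seq)}",
    ]
    lines.extend(body_features.rstrip("\n").splitlines())
    lines.append("ORIGIN")
    lines.extend(origin_lines)
    lines.append("//")
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path
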