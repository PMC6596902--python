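import pytest

from nrfatools.io import write_clade_map, write_fasta
from nrfatools.synthetic import miniature_panel


@pytest.fixture(scope="session")
def miniature():
    """The fixed 6-clade, 60-sequence panel with a planted coverage table."""
    return miniature_panel(seed=20240)


@pytest.fixture(scope="session")
def mini_bundle(tmp_path_factory, miniature):
    """The miniature panel written out as a FASTA/TSV/YAML file bundle."""
    root = tmp_path_factory.mktemp("mini_bundle")
    panel = miniature.panel
    write_fasta(panel.sequences, root / "panel.fasta")
    write_clade_map(panel.clade_map, root / "clades.tsv")
    panel.truth.to_csv(root / "truth.tsv", sep="\t", index=False)
    with open(root / "primers.yaml", "w") as fh:
        fh.write("primers:\n")
        for p in (panel.forward, panel.reverse):
            fh.write(
                f"  - name: {p.name}\n    sequence: {p.sequence}\n"
                f"    orientation: {p.orientation}\n"
            )
        fh.write(
            "sets:\n  - name: synthetic_pair\n"
            f"    forward: [{panel.forward.name}]\n"
            f"    reverse: {panel.reverse.name}\n"
        )
    return {
        "root": root,
        "fasta": root / "panel.fasta",
        "clades": root / "clades.tsv",
        "primers": root / "primers.yaml",
        "truth": root / "truth.tsv",
    }
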