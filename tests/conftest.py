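from __future__ import annotations

import numpy as np
import pytest

from baculokit import synth

#: fixed study-scale seed used by the recovery suite
SCALE_SEED = 11


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def scale_genome():
    """The genome-scale synthetic fixture: ~137 kb circular genome with
    100 ORFs and the seven reference-architecture repeat regions."""
    record, manifest = synth.generate(synth.dapu_scale_spec(seed=SCALE_SEED))
    return record, manifest


@pytest.fixture(scope="session")
def small_genome():
    """A small planted genome for fast per-module recovery tests."""
    spec = synth.SyntheticSpec(
        genome_len=12_000,
        orfs=[
            synth.OrfSpec(300, "+", "early"),
            synth.OrfSpec(450, "-", "late"),
            synth.OrfSpec(600, "+", "both"),
            synth.OrfSpec(390, "-", "none"),
        ],
        repeats=[
            synth.RepeatSpec("hr", 66, 5),
            synth.RepeatSpec("non_hr", 29, 6),
            synth.RepeatSpec("ac_rich", 12, 8),
        ],
        cne_like=156,
        seed=5,
    )
    return synth.generate(spec)


def write_genbank(path, record_id: str, sequence: str, circular: bool,
                  features: list[str], origin: bool = True) -> None:
    """Emit a minimal GenBank flat file for parser tests."""
    topo = "circular" if circular else "linear"
    lines = [
        f"LOCUS       {record_id:<17}{len(sequence):>11} bp    DNA     "
        f"{topo:<8} VRL 01-JAN-2015",
        "DEFINITION  synthetic parser fixture.",
        f"ACCESSION   {record_id}",
        f"VERSION     {record_id}.1",
        "KEYWORDS    .",
        "SOURCE      synthetic",
        "  ORGANISM  synthetic",
        "FEATURES             Location/Qualifiers",
    ]
    lines.extend(features)
    if origin:
        lines.append("ORIGIN")
        for i in range(0, len(sequence), 60):
            chunk = sequence[i : i + 60].lower()
            blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
            lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    path.write_text("\n".join(lines) + "\n")
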