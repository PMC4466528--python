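from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ghrecover.simulate import reverse_translate, synthetic_panel
from ghrecover.types import PipelineConfig, Read, ReferenceProtein, revcomp


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig(rng_seed=7)


@pytest.fixture
def small_panel() -> list[ReferenceProtein]:
    """Five short synthetic panel proteins across three families."""
    return synthetic_panel(seed=42, families=("GH5", "GH9", "GH10"),
                           per_family=2, length_range=(120, 160))[:5]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def tiling_reads(template: str, read_len: int, step: int,
                 prefix: str = "r", sample: str = "Z7",
                 orientations=None) -> list[Read]:
    """Error-free reads tiling a template every `step` nt (last read is
    anchored to the template end so the tiling always covers it)."""
    reads = []
    starts = list(range(0, max(len(template) - read_len, 0) + 1, step))
    if starts[-1] != len(template) - read_len:
        starts.append(len(template) - read_len)
    for i, s in enumerate(starts):
        seq = template[s:s + read_len]
        orient = orientations[i % len(orientations)] if orientations else "+"
        if orient == "-":
            seq = revcomp(seq)
        reads.append(Read(id=f"{prefix}{i:03d}", seq=seq, sample=sample))
    return reads


def gene_on_template(rng: np.random.Generator,
                     protein: ReferenceProtein,
                     flank: int = 300) -> tuple[str, tuple[int, int]]:
    """A template carrying one reverse-translated gene with random flanks."""
    gene = reverse_translate(protein.seq, rng)
    left = random_dna(rng, flank)
    right = random_dna(rng, flank)
    return left + gene + right, (flank, flank + len(gene))
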