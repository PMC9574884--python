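import numpy as np
import pytest

from ampliphase.demux import BarcodeManifest
from ampliphase.locus import demo_locus


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def locus():
    return demo_locus()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_manifest(
    n_forward: int = 3,
    n_backward: int = 3,
    barcode_length: int = 16,
    anchor_length: int = 256,
    seed: int = 777,
) -> BarcodeManifest:
    """Synthetic manifest with random (distinct) barcodes and anchors."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()

    def fresh(length):
        while True:
            seq = random_dna(rng, length)
            if seq not in seen:
                seen.add(seq)
                return seq

    fwd = {f"F{i}": fresh(barcode_length) for i in range(n_forward)}
    bwd = {f"B{i}": fresh(barcode_length) for i in range(n_backward)}
    sample_map = {
        (f"F{i}", f"B{j}"): f"s{i}_{j}"
        for i in range(n_forward)
        for j in range(n_backward)
    }
    return BarcodeManifest(
        forward_barcodes=fwd,
        backward_barcodes=bwd,
        sample_map=sample_map,
        anchor_forward=random_dna(rng, anchor_length),
        anchor_backward=random_dna(rng, anchor_length),
    )


@pytest.fixture
def manifest():
    return make_manifest()
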