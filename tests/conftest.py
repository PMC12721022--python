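import numpy as np
import pytest

from ribrot import (
    SubunitPartition,
    SyntheticAssemblySpec,
    analyze_rotation,
    apply_transform,
    generate_assembly_pair,
    kabsch_superpose,
    match_backbone,
)


@pytest.fixture
def partition():
    """Chain roles of the synthetic assemblies (R reference, M mobile)."""
    return SubunitPartition(reference_chains={"R"}, mobile_chains={"M"})


def run_synthetic_pipeline(spec: SyntheticAssemblySpec, config=None,
                           use_true_plane=False, atom_class="both"):
    """generate → match → superpose(reference) → rotation analysis.

    Returns ((plane, field, summary), manifest). With use_true_plane the
    analysis projects onto the generator's intended plane (normal = the
    true rotation axis) instead of fitting one.
    """
    part = SubunitPartition(reference_chains={"R"}, mobile_chains={"M"})
    model_a, model_b, manifest = generate_assembly_pair(spec)
    pairs = match_backbone(model_a, model_b, part, atom_class)
    aligned = apply_transform(pairs, kabsch_superpose(pairs, "reference"))
    plane = manifest.plane if use_true_plane else None
    return analyze_rotation(aligned, config, plane=plane), manifest


@pytest.fixture
def synthetic_pipeline():
    return run_synthetic_pipeline


def fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit directions (deterministic)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
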