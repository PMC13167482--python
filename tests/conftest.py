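import pytest

from ctdna_concord.simulate import SimConfig, VariantSpec


@pytest.fixture(scope="session")
def snv_variant() -> VariantSpec:
    return VariantSpec("chrS", 2000, "C", "T")


@pytest.fixture(scope="session")
def ins_variant() -> VariantSpec:
    return VariantSpec("chrS", 2000, "C", "CATG")


@pytest.fixture(scope="session")
def del_variant() -> VariantSpec:
    return VariantSpec("chrS", 2000, "CGTA", "C")


@pytest.fixture(scope="session", params=["SNV", "insertion", "deletion"])
def any_variant(request, snv_variant, ins_variant, del_variant) -> VariantSpec:
    return {"SNV": snv_variant, "insertion": ins_variant,
            "deletion": del_variant}[request.param]


def make_sim_config(variant: VariantSpec, **kwargs) -> SimConfig:
    defaults = dict(seed=11, variant=variant, n_fragments=400, mutant_fraction=0.3)
    defaults.update(kwargs)
    return SimConfig(**defaults)
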