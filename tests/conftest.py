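import pytest

from sigmapnet import (
    GeneratorSpec,
    MapModel,
    MapReaction,
    MapSpecies,
    ModifierSign,
    ReactionClass,
    SpeciesClass,
    build_reaction_graph,
    generate_map,
)


def make_species(sid, name=None, cls=SpeciesClass.PROTEIN, ref=None, **kw):
    name = name or sid
    if ref is None and cls is SpeciesClass.PROTEIN:
        ref = name.upper()
    return MapSpecies(
        species_id=sid,
        display_name=name,
        species_class=cls,
        protein_reference=ref or "",
        **kw,
    )


@pytest.fixture
def tiny_model():
    """A -> (R1) -> B, B -> (R2, inhibited by C) -> A, plus a lone gene."""
    species = [
        make_species("A"),
        make_species("B"),
        make_species("C"),
        make_species("g1", cls=SpeciesClass.GENE, ref=""),
    ]
    reactions = [
        MapReaction("R1", ReactionClass.STATE_TRANSITION, ("A",), ("B",)),
        MapReaction(
            "R2",
            ReactionClass.STATE_TRANSITION,
            ("B",),
            ("A",),
            modifiers=(("C", ModifierSign.INHIBITION),),
        ),
    ]
    return MapModel(species=species, reactions=reactions, name="tiny")


@pytest.fixture
def tiny_graph(tiny_model):
    return build_reaction_graph(tiny_model)


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down generator world for fast unit tests."""
    return GeneratorSpec(
        n_modules=3,
        molecules_per_module=(3, 5),
        states_per_molecule=(1, 2),
        tf_layer_size=2,
        n_planted_candidates=2,
        n_decoys=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_spec):
    return generate_map(small_spec)


@pytest.fixture(scope="session")
def default_world():
    return generate_map(GeneratorSpec(seed=0))
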