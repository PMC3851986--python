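import pytest

from pathatlas.model import (
    Alias,
    Entity,
    EntityClass,
    MapDocument,
    ModificationState,
    Reaction,
    Role,
    SpeciesState,
)


@pytest.fixture
def worked_example_doc() -> MapDocument:
    """Hand-built map around the classic worked examples of the naming
    grammar: phosphorylated Cdc25 in the cytoplasm and the Cdc13:Cdc2
    complex with Cdc2 phosphorylated on Thr167."""
    doc = MapDocument(name="worked_example")
    doc.entities = {
        "pr1": Entity("pr1", EntityClass.PROTEIN, "Cdc25",
                      "Identifiers:\nHUGO:CDC25A UNIPROT:P30304 "
                      "@biocyc:YEAST:G3O-30431\n"
                      "Maps_Modules:\nCellCycle\n"
                      "References:\nPMID:18319725 first description."),
        "pr2": Entity("pr2", EntityClass.PROTEIN, "Cdc13"),
        "pr3": Entity("pr3", EntityClass.PROTEIN, "Cdc2",
                      "Maps_Modules:\nCellCycle, Checkpoint"),
        "gn1": Entity("gn1", EntityClass.GENE, "GeneX"),
        "rn1": Entity("rn1", EntityClass.RNA, "RnaY"),
    }
    pho = ModificationState(state_label="Pho")
    thr167 = ModificationState(state_label="pho", residue_label="Thr167")
    doc.species_states = {
        "s1": SpeciesState("s1", (("pr1", ()),)),
        "s2": SpeciesState("s2", (("pr1", (pho,)),), compartment="cytoplasm"),
        "s3": SpeciesState(
            "s3", (("pr2", ()), ("pr3", (thr167,))), compartment="cytoplasm"
        ),
        "s4": SpeciesState("s4", (("gn1", ()),), compartment="nucleus"),
        "s5": SpeciesState("s5", (("rn1", ()),)),
        "s6": SpeciesState("s6", (("pr3", ()),)),
    }
    doc.aliases = {
        f"a{i}": Alias(f"a{i}", sid, (40.0 * i, 30.0 * i, 90.0, 36.0))
        for i, sid in enumerate(doc.species_states, start=1)
    }
    doc.reactions = {
        "re1": Reaction(
            "re1",
            (("s1", Role.REACTANT), ("s2", Role.PRODUCT), ("s3", Role.MODIFIER)),
            (("s3", "CATALYSIS"),),
        ),
        "re2": Reaction("re2", (("s4", Role.REACTANT), ("s5", Role.PRODUCT))),
    }
    return doc


@pytest.fixture(scope="session")
def fixture_map():
    """Default synthetic map (seed 1) plus its XML, shared across tests."""
    from pathatlas.fixtures import FixtureSpec, make_map

    spec = FixtureSpec(seed=1)
    doc, xml = make_map(spec)
    return spec, doc, xml
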