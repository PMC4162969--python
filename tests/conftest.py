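import numpy as np
import pytest

from crfref.corpus_io import QueryPair, Reference, Thesaurus, make_reference


@pytest.fixture
def gene_thesaurus():
    return Thesaurus(
        "gene",
        {
            "HBB": (("HBB",), ("beta", "globin"), ("hbs",)),
            "HBA": (("HBA",), ("alpha", "globin")),
            "NOS3": (("NOS3",), ("enos",)),
        },
    )


@pytest.fixture
def disease_thesaurus():
    return Thesaurus(
        "disease",
        {
            "scd": (("sickle", "cell", "disease"), ("sickle", "cell", "anemia")),
            "thal": (("beta", "thalassemia"),),
            "stroke": (("stroke",),),
        },
    )


@pytest.fixture
def pair():
    return QueryPair("p1", "HBB", "scd")


@pytest.fixture
def sickle_ref():
    """A small abstract mentioning the query gene and disease plus distractors."""
    return make_reference(
        "10791557",
        "Sickle cell disease and the beta globin gene",
        sentences=[
            "sickle cell disease is caused by a variant of the beta globin gene",
            "patients with stroke and alpha globin changes were reviewed",
            "we conclude that hbs explains sickle cell disease",
        ],
    )


def random_reference(rng: np.random.Generator, ref_id: str, thesauri, max_tokens=60):
    """A random document with random alias plantings, for oracle comparisons."""
    vocab = [f"w{i}" for i in range(30)]
    aliases = [a for t in thesauri for als in t.entries.values() for a in als]
    def region(n):
        toks = []
        while len(toks) < n:
            if rng.random() < 0.25:
                toks.extend(aliases[rng.integers(len(aliases))])
            else:
                toks.append(vocab[rng.integers(len(vocab))])
        return toks
    title = region(int(rng.integers(3, 9)))
    n_sent = int(rng.integers(1, 4))
    sents = [" ".join(region(int(rng.integers(4, max(5, max_tokens // n_sent)))))
             for _ in range(n_sent)]
    return make_reference(ref_id, " ".join(title), sentences=sents)
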