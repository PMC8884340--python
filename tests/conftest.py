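import pytest

from bifluent.lexicon import LexicalEntry, Lexicon, PhonemeInventory


@pytest.fixture(scope="session")
def inventory() -> PhonemeInventory:
    vowels = "aa ae ah ao aw ay eh er ey ih iy ow oy uh uw a e i o u".split()
    consonants = "b ch d dh f g hh jh k l m n ng p r rr s sh t th v w x y z zh ny".split()
    return PhonemeInventory(frozenset(vowels + consonants), frozenset(vowels))


def _entry(form, language, concept, category, tags, phones):
    return LexicalEntry(
        form=form,
        language=language,
        concept_id=concept,
        category=category,
        subcategories=frozenset(tags),
        phonemes=tuple(phones.split()),
    )


@pytest.fixture(scope="session")
def animal_lexicon(inventory) -> Lexicon:
    """Small bilingual animal lexicon matching the worked scoring examples."""
    rows = [
        ("dog", "perro", "c_dog", ["pets"], "d ao g", "p e rr o"),
        ("cat", "gato", "c_cat", ["pets"], "k ae t", "g a t o"),
        ("horse", "caballo", "c_horse", ["farm"], "hh ao r s", "k a b a y o"),
        ("pig", "cerdo", "c_pig", ["farm"], "p ih g", "s e r d o"),
        ("cow", "vaca", "c_cow", ["farm"], "k aw", "b a k a"),
        ("dolphin", "delfín", "c_dolphin", ["water"], "d aa l f ih n", "d e l f i n"),
        ("fish", "pez", "c_fish", ["pets", "water"], "f ih sh", "p e s"),
        ("fox", "zorro", "c_fox", ["forest"], "f aa k s", "s o rr o"),
    ]
    entries = []
    for en, es, concept, tags, en_ph, es_ph in rows:
        entries.append(_entry(en, "english", concept, "animals", tags, en_ph))
        entries.append(_entry(es, "spanish", concept, "animals", tags, es_ph))
    # out-of-category items for intrusion/letter scenarios
    entries.append(_entry("apple", "english", "c_apple", "food", ["fruits"], "ae p ah l"))
    entries.append(
        _entry("manzana", "spanish", "c_apple", "food", ["fruits"], "m a n s a n a")
    )
    return Lexicon(entries, inventory)


@pytest.fixture(scope="session")
def phonemic_lexicon(inventory) -> Lexicon:
    """Letter-task words exercising all four phonemic-linkage criteria."""
    rows = [
        ("art", "aa r t"),
        ("arm", "aa r m"),
        ("fat", "f ae t"),
        ("fit", "f ih t"),
        ("foot", "f uh t"),
        ("sand", "s ae n d"),
        ("stand", "s t ae n d"),
        ("sum", "s ah m"),
        ("some", "s ah m"),
        ("dog", "d ao g"),
        ("fish", "f ih sh"),
    ]
    entries = [
        _entry(form, "english", f"w_{form}", None, [], phones)
        for form, phones in rows
    ]
    return Lexicon(entries, inventory)


@pytest.fixture(scope="session")
def packaged_lexicon():
    from bifluent.cohort import default_lexicon

    return default_lexicon()


@pytest.fixture(scope="session")
def cohort_spec():
    from bifluent.cohort import default_cohort_spec

    return default_cohort_spec()
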