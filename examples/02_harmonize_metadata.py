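"""Controlled-vocabulary harmonization of a messy metadata sheet.

Incoming sheets say "M"/"F" and "SLE"; the warehouse vocabulary says
male/female and lupus. Unmapped values reject the load; explicit value
maps (the scriptable equivalent of interactive drag-and-drop) fix it.
"""

import pandas as pd

from immunomart import (ColumnMapping, VocabularyError, create_store,
                        load_metadata, seed_default_vocabularies)

store = create_store(":memory:")
seed_default_vocabularies(store)

sheet = pd.DataFrame({
    "ID": ["P1", "P2", "P3"],
    "Sex": ["M", "F", "F"],
    "Diagnosis": ["SLE", "SLE", "healthy"],
})
colmap = ColumnMapping({"ID": "person_id", "Sex": "gender",
                        "Diagnosis": "condition"})

try:
    load_metadata(store, sheet, colmap)
except VocabularyError as exc:
    print("rejected as expected:", exc)

summary = load_metadata(store, sheet, colmap,
                        value_maps={"gender": {"M": "male", "F": "female"},
                                    "condition": {"SLE": "lupus"}})
print(f"loaded {summary.persons_created} persons after mapping")
for row in store.execute("SELECT person_id_ext, gender, condition"
                         " FROM person"):
    print("  stored:", row)
store.close()

# Every stored value is now a member of the controlled vocabulary, so
# "SLE" uploaded by one lab and "lupus" by another land as the same term.
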