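{
  "version": "1",
  "rules": [
    {"concept": "species", "value_label": "Rats", "method": "mesh", "mesh_term": "Rats"},
    {"concept": "species", "value_label": "Mice", "method": "mesh", "mesh_term": "Mice"},
    {"concept": "species", "value_label": "Guinea pigs", "method": "mesh", "mesh_term": "Guinea pigs"},
    {"concept": "electrode_type", "value_label": "Patch-clamp", "method": "both", "pattern": "whole[ -]cell|patch[ -]clamp", "mesh_term": "Patch-clamp techniques"},
    {"concept": "electrode_type", "value_label": "Sharp", "method": "regex", "pattern": "sharp electrode"},
    {"concept": "strain", "value_label": "Fischer 344", "method": "mesh", "mesh_term": "Rats, Inbred F344", "implies_species": "Rats"},
    {"concept": "strain", "value_label": "Long-Evans", "method": "mesh", "mesh_term": "Rats, Long-Evans", "implies_species": "Rats"},
    {"concept": "strain", "value_label": "Sprague-Dawley", "method": "mesh", "mesh_term": "Rats, Sprague-Dawley", "implies_species": "Rats"},
    {"concept": "strain", "value_label": "Wistar", "method": "mesh", "mesh_term": "Rats, Wistar", "implies_species": "Rats"},
    {"concept": "strain", "value_label": "C57BL", "method": "mesh", "mesh_term": "Mice, Inbred C57BL", "implies_species": "Mice"},
    {"concept": "strain", "value_label": "BALB C", "method": "mesh", "mesh_term": "Mice, Inbred BALB C", "implies_species": "Mice"},
    {"concept": "preparation_type", "value_label": "In vitro", "method": "regex", "pattern": "\\bslices?\\b|in vitro"},
    {"concept": "preparation_type", "value_label": "In vivo", "method": "regex", "pattern": "in vivo"},
    {"concept": "preparation_type", "value_label": "Cell culture", "method": "both", "pattern": "\\bcultures?d?\\b", "mesh_term": "Cell culture techniques"},
    {"concept": "preparation_type", "value_label": "Model", "method": "both", "pattern": "\\bmodel\\b", "mesh_term": "Computer simulation"}
  ]
}
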