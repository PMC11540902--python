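# Controlled vocabulary for parsing free-text quota notes.
#
# Each canonical code maps to the set of surface forms that may appear in a
# note (matched case- and whitespace-insensitively after NFC normalization).
# The grammar splits a note on commas and the word "and", classifies each
# token against these tables, and defaults any unconstrained dimension
# (terms -> ALL, sources -> wild, purposes -> ALL unless "all" is present).

terms:
  live: [live, live individuals, live specimens, live animals]
  skins: [skins, skin]
  skin_pieces: [skin pieces, small leather pieces, leather pieces, leather products, skin products]
  meat: [meat]
  trophies: [trophies, trophy]
  eggs: [eggs, egg]
  bodies: [bodies, body]
  shells: [shells, shell]
  tails: [tails, tail]
  sides: [sides, side]
  bellies: [bellies, belly]
  skulls: [skulls, skull]

sources:
  wild: [wild, wild-taken, wild taken, wild-sourced, wild sourced, wild-caught, wild caught, w]
  captive: [captive-bred, captive bred, captive, captive-born, captive born, f1, f1 captive, c, f]
  ranched: [ranched, ranch-raised, ranched specimens, r]

purposes:
  commercial: [commercial, commercial purposes, t]
  hunting: [hunting, hunting trophy, hunting trophies, h]
  personal: [personal, personal purposes, p]
  scientific: [scientific, scientific purposes, s]

# The universal token: alone it widens every dimension; paired with detail it
# widens only the dimensions left unconstrained by the detail.
all_tokens: [all, all trade]

# Terms countable as whole animals.  A term set is "comparable" (convertible
# to a count of individuals) iff every member is in this list; a quota mixing
# e.g. skins with meat cannot be expressed as one number of animals.
countable_terms: [live, skins, trophies, eggs, bodies, shells, tails, skulls]

# Malaysian regional tags: quotas published separately per region are summed
# to one national quota before compliance matching.
regions:
  sabah: [sabah]
  sarawak: [sarawak]
  peninsular: [peninsular malaysia, peninsular]
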