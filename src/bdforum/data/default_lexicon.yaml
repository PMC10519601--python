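# Bundled open affect lexicon for the five analysis categories.
# Small by design: seeded from the categories' canonical example vocabulary
# (love/nice/sweet; worried/fearful; hate/kill/annoyed; crying/grief/sad;
# I/me/mine) and extended with common inflections and stems. Externally
# licensed dictionaries can be supplied in .dic format instead.
version: bdforum-open-0.1
posemo:
  - love
  - loves
  - loved
  - loving
  - nice
  - sweet
  - happy
  - happier
  - happiness
  - good
  - great
  - glad
  - joy*
  - hope
  - hopeful
  - hoping
  - wonderful
  - excit*
anxiety:
  - worried
  - worri*
  - worry
  - worrying
  - fear
  - fearful
  - fears
  - anxious
  - anxiety
  - nervous
  - afraid
  - scared
  - panic*
  - tense
anger:
  - hate
  - hated
  - hates
  - hating
  - kill*
  - annoyed
  - annoying
  - angry
  - anger
  - mad
  - furious
  - rage
  - raging
sadness:
  - crying
  - cry
  - cries
  - cried
  - grief
  - griev*
  - sad
  - sadness
  - sadly
  - depress*
  - miserable
  - hopeless
  - tear
  - tears
  - lonely
i:
  - i
  - me
  - my
  - mine
  - myself
  - i'm
  - i've
  - i'll
  - i'd
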