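# Default topic lexicon: 15 nicotine-conversation topics and their matchable
# patterns.  This lexicon is a RECONSTRUCTION from the published topic
# descriptions (the original study's pattern lists are unpublished); edit
# freely.  Pattern kinds:
#   unigram       - single token present anywhere
#   bigram        - two tokens adjacent, in order
#   ordered_group - tokens occur in order, gaps allowed
# Tokens are written in surface form; they are passed through the same
# normalization (lower-casing, character stripping, lemmatization) as tweet
# text when the lexicon is loaded, so matching is always consistent.
topics:
  person tagging:
    - unigram: "@person"
  addiction:
    - unigram: addicted
    - unigram: addict
    - unigram: addiction
    - unigram: addictive
    - unigram: craving
    - unigram: hooked
  appeal:
    - ordered_group: love nicotine
    - ordered_group: like nicotine
    - ordered_group: enjoy nicotine
  NRT:
    - unigram: patch
    - unigram: gum
    - unigram: nrt
    - ordered_group: nicotine replacement
  vaping:
    - unigram: vape
    - unigram: vaping
    - unigram: juul
    - unigram: e-cigarette
    - unigram: ecig
  smoking:
    - unigram: smoking
    - unigram: smoke
    - unigram: cigarette
    - unigram: cig
    - unigram: cigar
    - unigram: tobacco
  nicotine health risks:
    - ordered_group: nicotine brain
    - ordered_group: nicotine lungs
    - ordered_group: nicotine health
    - ordered_group: nicotine risks
    - ordered_group: amount nicotine
    - bigram: health risk
  withdrawal:
    - unigram: withdrawal
    - unigram: withdrawals
    - unigram: withdrawing
  quit nicotine:
    - bigram: cold turkey
    - bigram: nicotine free
    - ordered_group: quit nicotine
  cessation:
    - unigram: cessation
    - ordered_group: quit smoking
    - ordered_group: stop smoking
  polysubstance use:
    - ordered_group: alcohol nicotine
    - ordered_group: nicotine alcohol
    - ordered_group: beer nicotine
    - ordered_group: nicotine beer
    - ordered_group: vodka nicotine
    - ordered_group: nicotine vodka
  caffeine:
    - unigram: caffeine
    - unigram: coffee
  underage use:
    - unigram: underage
    - bigram: high school
    - ordered_group: teens nicotine
    - ordered_group: nicotine teens
    - ordered_group: kids nicotine
    - ordered_group: nicotine kids
    - ordered_group: children nicotine
    - ordered_group: nicotine children
  new products:
    - bigram: nicotine shot
    - ordered_group: supplement nicotine
    - ordered_group: nicotine supplement
    - ordered_group: boost nicotine
    - ordered_group: nicotine eliquid
  nicotine is safe:
    - ordered_group: nicotine safe
    - ordered_group: nicotine harmless
    - ordered_group: safe nicotine
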