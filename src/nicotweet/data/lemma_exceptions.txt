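# Irregular-form exceptions for the dictionary lemmatizer: "inflected lemma".
# Suffix rules handle regular inflection; only forms the rules miss go here.
children child
child child
teeth tooth
feet foot
men man
women woman
people person
mice mouse
geese goose
went go
gone go
going go
goes go
being be
doing do
having have
using use
making make
taking take
took take
taken take
giving give
gave give
given give
getting get
got get
gotten get
bought buy
buying buy
thought think
felt feel
kept keep
left leave
found find
told tell
said say
saying say
made make
came come
coming come
seen see
saw see
knew know
known know
dying die
dies die
died die
lying lie
tries try
trying try
tried try
quitting quit
quits quit
quit quit
always always
morning morning
evening evening
news news
better good
best good
worse bad
worst bad
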