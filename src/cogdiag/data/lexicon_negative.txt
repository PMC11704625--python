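sad
unhappy
miserable
depressed
depressing
gloomy
blue
down
low
upset
angry
mad
furious
annoyed
annoying
irritated
irritating
frustrated
frustrating
worried
worry
anxious
anxiety
nervous
afraid
scared
fearful
terrified
dread
tired
exhausted
fatigued
weary
drained
sleepy
sluggish
weak
sick
ill
unwell
ache
aching
pain
painful
hurt
hurting
sore
dizzy
confused
confusing
forgetful
forgot
forget
lost
lonely
alone
isolated
bored
boring
dull
empty
hopeless
helpless
worthless
guilty
ashamed
embarrassed
regret
regretful
disappointed
disappointing
discouraged
stressed
stressful
overwhelmed
troubled
trouble
difficult
hard
struggle
struggled
struggling
awful
terrible
horrible
bad
worse
worst
unpleasant
uncomfortable
restless
sleepless
cold
dark
dreary
bleak
grim
cranky
grumpy
tearful
crying
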