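happy
joy
joyful
glad
great
wonderful
lovely
pleasant
delighted
delightful
cheerful
content
contented
satisfied
grateful
thankful
blessed
excited
exciting
fun
enjoyed
enjoyable
enjoy
love
loved
loving
beautiful
bright
sunny
warm
calm
peaceful
relaxed
relaxing
refreshed
energetic
energized
strong
healthy
proud
accomplished
productive
successful
hopeful
optimistic
positive
good
better
best
fine
nice
kind
friendly
welcoming
laughed
laughing
smile
smiled
smiling
amused
amusing
interesting
interested
fascinating
curious
inspired
inspiring
uplifting
encouraged
encouraging
comfortable
cozy
festive
celebrated
celebration
victory
winning
thrilled
thrilling
marvelous
splendid
superb
terrific
fantastic
amazing
awesome
brilliant
charming
vibrant
lively
fresh
serene
tranquil
gentle
caring
supportive
connected
fulfilled
rewarding
pleased
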